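running	run
ran	run
runs	run
coughing	cough
coughs	cough
coughed	cough
viruses	virus
fevers	fever
prayed	pray
praying	pray
prays	pray
hospitals	hospital
masks	mask
children	child
feet	foot
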