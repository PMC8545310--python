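mom	mother
mum	mother
dad	father
doc	doctor
influenza	flu
grippe	flu
ill	sick
unwell	sick
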