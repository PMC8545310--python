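pray
for
my
mother
father
flu
fever
cough
virus
mask
stay
home
wash
hands
hospital
doctor
health
sick
love
family
work
school
vote
rain
music
game
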