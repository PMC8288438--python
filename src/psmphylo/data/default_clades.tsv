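clade_name
seed_plants
angiosperms
monocots
commelinids
magnoliids
eudicots
core_eudicots
superrosids
rosids
fabids
malvids
superasterids
asterids
lamiids
campanulids
Malpighiales
Caryophyllales
Ericales
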