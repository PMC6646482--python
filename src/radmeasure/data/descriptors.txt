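# RadLex-style descriptors (qualifiers of a finding)
scattered
multiple
solitary
single
diffuse
focal
bilateral
unilateral
ill-defined
well-defined
well-circumscribed
poorly defined
spiculated
lobulated
irregular
smooth
round
ovoid
linear
punctate
tiny
small
large
bulky
subtle
prominent
conspicuous
heterogeneous
homogeneous
hypodense
hyperdense
isodense
hypoechoic
hyperechoic
anechoic
hypointense
hyperintense
calcified
noncalcified
cystic
solid
necrotic
hemorrhagic
fatty
sclerotic
lytic
blastic
nodular
confluent
peripheral
central
stable
new
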