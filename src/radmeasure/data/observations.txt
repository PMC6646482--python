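# Imaging observations (findings being measured)
nodule
mass
lesion
cyst
lymph node
node
opacity
ground-glass opacity
consolidation
effusion
pleural effusion
pericardial effusion
ascites
metastasis
tumor
neoplasm
calcification
granuloma
hemangioma
adenoma
adenopathy
lymphadenopathy
thrombus
aneurysm
stenosis
stricture
dilatation
ectasia
hernia
abscess
fluid collection
collection
hematoma
infarct
edema
atelectasis
fibrosis
scarring
thickening
wall thickening
enhancing
enhancement
hypodensity
hyperdensity
hypointensity
hyperintensity
density
focus
defect
fracture
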