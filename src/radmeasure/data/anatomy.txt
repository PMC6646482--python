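# Anatomical entities (one per line, lowercase; '#' starts a comment)
liver
right hepatic lobe
left hepatic lobe
hepatic lobe
caudate lobe
spleen
pancreas
pancreatic head
pancreatic tail
gallbladder
kidney
left kidney
right kidney
renal cortex
adrenal gland
left adrenal gland
right adrenal gland
lung
left lung
right lung
left upper lobe
left lower lobe
right upper lobe
right middle lobe
right lower lobe
lingula
pleura
mediastinum
hilum
left hilum
right hilum
thyroid
thyroid lobe
left thyroid lobe
right thyroid lobe
breast
left breast
right breast
axilla
left axilla
right axilla
frontal
left frontal
right frontal
lateral right frontal
lateral left frontal
frontal lobe
parietal lobe
temporal lobe
occipital lobe
cerebellum
left cerebellar
right cerebellar
cerebellar hemisphere
brainstem
pons
thalamus
basal ganglia
corpus callosum
pituitary
orbit
left orbit
right orbit
neck
retroperitoneum
peritoneum
omentum
mesentery
abdomen
pelvis
bladder
prostate
uterus
cervix
ovary
left ovary
right ovary
rectum
sigmoid colon
ascending colon
transverse colon
descending colon
cecum
ileum
duodenum
stomach
esophagus
aorta
inferior vena cava
portal vein
common bile duct
iliac chain
inguinal region
femur
humerus
vertebral body
sacrum
ilium
rib
sternum
clavicle
scapula
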