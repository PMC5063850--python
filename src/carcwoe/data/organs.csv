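code,name,system
adr,adrenal gland,endocrine
bm,bone marrow,hematopoietic
bo,bone,musculoskeletal
br,brain,nervous
ce,cecum (inferred from context),gastrointestinal
col,colon,gastrointestinal
epi,epididymis,reproductive
gon,gonads,reproductive
hrt,heart,cardiovascular
hsyst,hematopoietic system,hematopoietic
int,intestine,gastrointestinal
islet,pancreatic islets,endocrine
kid,kidney,urinary
li,liver,hepatobiliary
ln,lymph node,hematopoietic
lu,lung,respiratory
mam,mammary gland,reproductive
many,multiple organs,systemic
mes,mesentery,gastrointestinal
nose,nasal cavity,respiratory
oral,oral mucosa,gastrointestinal
ova,ovary,reproductive
pan,"pancreas, exocrine",gastrointestinal
parath,parathyroid gland,endocrine
pit,pituitary gland,endocrine
pros,prostate,reproductive
sgl,salivary gland,gastrointestinal
sk,skin (variant token),integumentary
skin,skin,integumentary
soft t,soft tissue,musculoskeletal
spl,spleen,hematopoietic
stom,stomach/forestomach,gastrointestinal
te,testis (variant token),reproductive
tes,testis,reproductive
thy,thymus,hematopoietic
thym,thymus (variant token),hematopoietic
thyr,thyroid gland,endocrine
UGT,urogenital tract/urinary bladder,urinary
ut,uterus,reproductive
vag,vagina,reproductive
zymgl,Zymbal gland,integumentary
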