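code,name,behavior
ac,adenocarcinoma/carcinoma,malignant
ad,adenoma,benign
ad/ca,adenoma/carcinoma,unspecified
astr,astrocytoma,malignant
baca,basal cell carcinoma,malignant
bhaem,benign hemangioma,benign
bpha,benign pheochromocytoma,benign
bthym,benign thymoma,benign
ca,carcinoma,malignant
fad,fibroadenoma,benign
fibr,fibroma,benign
gca,granulosa cell tumor,benign
gli,glioma,malignant
leio,leiomyoma,benign
leu,leukemia,malignant
lip,lipoma,benign
lymph,lymphoma,malignant
mel,melanoma,malignant
most,osteoma/osteosarcoma (inferred from context),unspecified
mpha,malignant pheochromocytoma,malignant
pap,papilloma,benign
polyp,polyp,benign
sar,sarcoma,malignant
SCC,squamous cell carcinoma,malignant
schwan,schwannoma,unspecified
SCP,squamous cell papilloma,benign
tu,"tumor, unspecified behavior",unspecified
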