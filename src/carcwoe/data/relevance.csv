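organ,morphology,human_relevant,rationale
ut,ac,false,"uterine endometrial adenocarcinoma, common spontaneous tumor of aged female rats"
pan,*,false,"pancreatic acinar cell tumors, spontaneous in aged rats"
islet,*,false,"pancreatic islet cell neoplasia, spontaneous in aged rats"
adr,*,false,"adrenal medullary pheochromocytoma, rodent-specific via catecholamine/Ca2+ feedback"
stom,*,false,forestomach tumors; organ absent in humans
thyr,*,false,"thyroid follicular cell tumors, rat-specific T3/T4 clearance feedback"
pit,*,false,"pituitary adenohypophysis tumors, very common spontaneously in aged rats"
tes,*,false,"Leydig (interstitial) cell tumors, LH-feedback mechanism specific to rats"
UGT,*,false,"urinary bladder tumors, crystalluria-mediated in rat"
mam,*,false,"mammary gland tumors, highest-incidence spontaneous neoplasm of aged female rats"
*,ad,false,benign adenoma
*,fad,false,benign fibroadenoma
*,polyp,false,benign polyp
*,pap,false,benign papilloma
*,fibr,false,benign fibroma
*,leio,false,benign leiomyoma
*,bhaem,false,benign hemangioma
*,schwan,false,"uterine schwannoma, spontaneous in aged rats"
*,gca,false,benign granulosa cell tumor
*,SCP,false,benign squamous cell papilloma
*,bpha,false,benign pheochromocytoma
*,leu,false,"mononuclear cell leukemia, common spontaneous neoplasm of aged rats"
*,lymph,false,spontaneous hematopoietic neoplasm of aged rats
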