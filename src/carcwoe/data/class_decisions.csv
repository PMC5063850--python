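class_id,table_of_origin,decision,n_compounds,n_with_tumors
"AB, bactericidal",none,NT,1,0
"AB, fluoroquinolones",positive,NT,3,3
"AF, allylamine derivative",none,NT,1,1
"AF, benzimidazole",none,NT,1,0
"AF, conazole derivatives",positive,NT,3,3
"AI, COX-2 inhibitors",mixed,TN,4,2
"AI, NSAIDs",negative,TN,12,2
"AM, antimalarial",none,NT,1,0
"AM, antiparasitic",none,NT,1,0
"AM, antivirals",mixed,NT,10,4
"BM, bisphosphonates",negative,TN,3,0
"CNS, 5HT1b/d agonists",mixed,TN,4,2
"CNS, 5HT2 antagonists",positive,NC,2,2
"CNS, 5HT3 antagonists",mixed,TN,2,1
"CNS, COMT inhibitor",none,NC,1,1
"CNS, DA2 agonists",positive,TP,4,4
"CNS, DA2 antagonists",positive,TP,4,3
"CNS, SNRIs",mixed,TN,4,2
"CNS, SSRIs",negative,TN,7,1
"CNS, alpha2-delta agonist",none,NC,1,1
"CNS, antiepileptic Na-channel blockers",mixed,TN,6,2
"CNS, benzodiazepines",mixed,TN,5,2
"CNS, mu-opioid agonists",mixed,TN,3,1
"CNS, mu-opioid antagonists",negative,TN,2,0
"CNS, tetracyclic antidepressant",none,NC,1,1
"CVS, ACE inhibitors",mixed,TN,11,7
"CVS, Na-channel blockers",mixed,TN,3,1
"CVS, PDE3 inhibitors",mixed,TN,2,1
"CVS, adrenergic alpha1 agonists",mixed,TN,2,1
"CVS, adrenergic alpha1 antagonist with 5-HT1A affinity",none,TN,1,0
"CVS, adrenergic alpha1 antagonists",mixed,TP,7,3
"CVS, adrenergic alpha2 agonists",mixed,TN,3,1
"CVS, adrenergic beta antagonists",negative,TN,13,4
"CVS, angiotensin II antagonists",negative,TN,5,0
"CVS, anticoagulants",mixed,TN,2,1
"CVS, calcium antagonists",positive,TN,12,8
"CVS, class 1C antiarrhythmics",negative,TN,2,0
"CVS, endothelin antagonists",negative,TN,2,0
"CVS, imidazoline agonists",mixed,TN,2,1
"CVS, loop diuretics",positive,NC,4,3
"CVS, platelet aggregation inhibitors",mixed,NC,2,1
"CVS, vasopressin-2 agonists",negative,TN,2,0
"GI, 5HT4 agonists",positive,TN,3,2
"GI, histamine H2 antagonists",mixed,TN,4,2
"GI, proton pump inhibitors",positive,TP,4,3
"HM, GnRH agonists",positive,TP,5,4
"HM, antiandrogen",none,TP,1,1
"HM, aromatase inhibitor",none,TP,1,1
"HM, dual 5-reductase inhibitors",positive,TP,2,2
"HM, estrogen agonists",positive,TP,2,2
"HM, progestogen (combinations)",positive,TP,3,2
"HM, selective estrogen receptor modulators",positive,TP,2,2
"IS, immunomodulators",mixed,NC,2,1
"IS, immunosuppressives",negative,TP,6,0
"MB, DPP4 inhibitors",negative,TN,4,0
"MB, HMG-CoA reductase inhibitors",positive,TP,5,3
"MB, alpha-glucosidase inhibitors",mixed,TN,2,1
"MB, fibrates",positive,TP,3,2
"RS, adrenergic beta2 agonists",positive,TP,5,5
"RS, anticholinergics",negative,TN,2,0
"RS, antifibrotic",none,NC,1,1
"RS, corticosteroids",positive,TP,3,3
"RS, histamine H1 antagonists",mixed,TN,7,2
"RS, leukotriene receptor antagonist",none,TN,1,0
"RS, mast cell stabilizer",none,TN,1,0
"RS, methylxanthine derivative",none,TN,1,1
"UB, anticholinergics",mixed,TN,6,3
single:1,none,TN,1,0
single:7,none,TN,1,0
single:20,none,TN,1,0
single:22,none,TN,1,0
single:28,none,TN,1,0
single:30,none,TN,1,0
single:32,none,TN,1,0
single:36,none,TN,1,0
single:39,none,TN,1,0
single:43,none,TN,1,0
single:56,none,TN,1,0
single:57,none,TN,1,0
single:58,none,TN,1,0
single:62,none,TN,1,0
single:63,none,TN,1,0
single:70,none,TN,1,0
single:75,none,TN,1,0
single:78,none,TN,1,0
single:79,none,TN,1,0
single:80,none,TN,1,0
single:81,none,TN,1,0
single:89,none,TN,1,0
single:96,none,TN,1,0
single:102,none,TN,1,0
single:106,none,TN,1,0
single:109,none,TN,1,0
single:113,none,TN,1,0
single:118,none,TN,1,0
single:119,none,TN,1,0
single:122,none,TN,1,0
single:130,none,TN,1,0
single:134,none,TP,1,0
single:136,none,TN,1,0
single:138,none,TN,1,0
single:141,none,TN,1,0
single:151,none,TN,1,0
single:153,none,TN,1,0
single:160,none,TN,1,0
single:169,none,TP,1,1
single:177,none,TP,1,1
single:196,none,TN,1,1
single:197,none,TN,1,1
single:198,none,TN,1,1
single:213,none,TP,1,1
single:216,none,TN,1,1
single:223,none,TN,1,1
single:225,none,TN,1,1
single:232,none,TN,1,1
single:234,none,TN,1,1
single:238,none,TN,1,1
single:258,none,TP,1,1
single:261,none,TN,1,1
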