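mode_of_action_pattern,class_id
"AB, fluoroquinolone","AB, fluoroquinolones"
"AB, remaining, bactericidal","AB, bactericidal"
"AF, conazole derivative","AF, conazole derivatives"
"AF, remaining, allylamine derivative","AF, allylamine derivative"
"AF, remaining, benzimidazole","AF, benzimidazole"
"AI, COX2 inhibitor","AI, COX-2 inhibitors"
"AI, NSAID","AI, NSAIDs"
"AM, remaining, antimalarial","AM, antimalarial"
"AM, remaining, antiparasite","AM, antiparasitic"
AV,"AM, antivirals"
"AV, CCR5 receptor antagonist","AM, antivirals"
"AV, guanosine analog","AM, antivirals"
"AV, hepatitis B-inhibitor","AM, antivirals"
"AV, herpes genitalis","AM, antivirals"
"AV, immunostimulant","AM, antivirals"
"AV, nucleoside inhibitor","AM, antivirals"
"AV, protease inhibitor","AM, antivirals"
"AV, viral DNA polymerase inhibitor","AM, antivirals"
"BM, bisphosphonate","BM, bisphosphonates"
"CNS, 5-HT1b/d agonist","CNS, 5HT1b/d agonists"
"CNS, 5-HT2 antagonist","CNS, 5HT2 antagonists"
"CNS, 5-HT3 antagonist","CNS, 5HT3 antagonists"
"CNS, 5HT2 antagonist","CNS, 5HT2 antagonists"
"CNS, DA2 agonist","CNS, DA2 agonists"
"CNS, DA2 antagonist","CNS, DA2 antagonists"
"CNS, DA2-antagonist, DA3 antagonist","CNS, DA2 antagonists"
"CNS, DA2-antagonist, benzamide","CNS, DA2 antagonists"
"CNS, DA2-antagonist/5-HT antagonist","CNS, DA2 antagonists"
"CNS, SNRI","CNS, SNRIs"
"CNS, SSRI","CNS, SSRIs"
"CNS, SSRI, 5-HT antagonist","CNS, SSRIs"
"CNS, antiepileptic, Na-channel blocker","CNS, antiepileptic Na-channel blockers"
"CNS, benzodiazepine","CNS, benzodiazepines"
"CNS, benzodiazepine-like hypnotic","CNS, benzodiazepines"
"CNS, opioid, μ-agonist","CNS, mu-opioid agonists"
"CNS, opioid, μ-agonist, anticholinergic","CNS, mu-opioid agonists"
"CNS, opioid, μ-antagonist","CNS, mu-opioid antagonists"
"CNS, remaining, COMT-inhibitor","CNS, COMT inhibitor"
"CNS, remaining, antidepressant","CNS, tetracyclic antidepressant"
"CNS, remaining, α2-delta agonist","CNS, alpha2-delta agonist"
"CVS, ACE inhibitor","CVS, ACE inhibitors"
"CVS, Na-channel block","CVS, Na-channel blockers"
"CVS, PDE3 inhibitor","CVS, PDE3 inhibitors"
"CVS, angiotensin II antagonist","CVS, angiotensin II antagonists"
"CVS, anticoagulant","CVS, anticoagulants"
"CVS, calcium antagonist","CVS, calcium antagonists"
"CVS, class 1C antiarrhythmic","CVS, class 1C antiarrhythmics"
"CVS, endothelin antagonist","CVS, endothelin antagonists"
"CVS, imidazoline agonist","CVS, imidazoline agonists"
"CVS, loop diuretic","CVS, loop diuretics"
"CVS, platelet aggregation inhibitor","CVS, platelet aggregation inhibitors"
"CVS, vasopressin-2 agonist","CVS, vasopressin-2 agonists"
"CVS, α1 agonist","CVS, adrenergic alpha1 agonists"
"CVS, α1 antagonist","CVS, adrenergic alpha1 antagonists"
"CVS, α1 antagonist and 5-HT1A","CVS, adrenergic alpha1 antagonist with 5-HT1A affinity"
"CVS, α2 agonist","CVS, adrenergic alpha2 agonists"
"CVS, α2 agonist, ocular","CVS, adrenergic alpha2 agonists"
"CVS, β antagonist","CVS, adrenergic beta antagonists"
"CVS, β antagonist/α1 blocker","CVS, adrenergic beta antagonists"
"GI, 5-HT4 agonist","GI, 5HT4 agonists"
"GI, 5HT4 agonist","GI, 5HT4 agonists"
"GI, histamine H2 antagonist","GI, histamine H2 antagonists"
"GI, proton pump inhibitor","GI, proton pump inhibitors"
"HM, GnRH agonist","HM, GnRH agonists"
"HM, dual 5-reductase inhibitor","HM, dual 5-reductase inhibitors"
"HM, estrogen agonist","HM, estrogen agonists"
"HM, progesterone antagonist, birth cont","HM, progestogen (combinations)"
"HM, progestogen–estrogen contraceptive","HM, progestogen (combinations)"
"HM, remaining, antiandrogen","HM, antiandrogen"
"HM, remaining, aromatase inhibitor","HM, aromatase inhibitor"
"HM, selective estrogen modulator","HM, selective estrogen receptor modulators"
"IS, immunosuppressive","IS, immunosuppressives"
"IS, immunosuppressive, S1P antagonist","IS, immunosuppressives"
"IS, immunosuppressive, mTOR inhibitor","IS, immunosuppressives"
"IS, remaining","IS, immunomodulators"
"IS, remaining, imidazothiazole derivative","IS, immunomodulators"
"MB, HMG-CoA reductase inhibitor","MB, HMG-CoA reductase inhibitors"
"MB, antidiabetic, DPP4 inhibitor","MB, DPP4 inhibitors"
"MB, antidiabetic, α-glucosidase inhib","MB, alpha-glucosidase inhibitors"
"MB, antidiabetic, α-glucosidase inhibitor","MB, alpha-glucosidase inhibitors"
"MB, fibrate","MB, fibrates"
"RS, anticholinergic","RS, anticholinergics"
"RS, corticosteroid","RS, corticosteroids"
"RS, histamine H1 antagonist","RS, histamine H1 antagonists"
"RS, remaining, antifibrotic","RS, antifibrotic"
"RS, remaining, leukotriene receptor antagonist","RS, leukotriene receptor antagonist"
"RS, remaining, mast cell stabilizer","RS, mast cell stabilizer"
"RS, remaining, methylxanthine-derivate","RS, methylxanthine derivative"
"RS, β2 agonist","RS, adrenergic beta2 agonists"
"UB, anticholinergic","UB, anticholinergics"
"UB, anticholinergic and calcium antagonist","UB, anticholinergics"
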