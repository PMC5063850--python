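# carcwoe

Weight-of-evidence prediction of rat carcinogenicity for non-genotoxic
pharmaceuticals, from subchronic (3–6 month) histopathology combined with
pharmacological class knowledge.

## The problem

Two-year rat carcinogenicity studies are the regulatory standard for
pharmaceuticals given chronically to patients, yet they are slow, expensive
and animal-intensive, and their human relevance is debated. A candidate
replacement is a weight-of-evidence argument assembled from data already in
hand at the end of Phase II: did the subchronic study show *putative
preneoplastic* lesions, and does the compound's pharmacological class have a
known proliferative mechanism?

`carcwoe` implements that argument as a tested, auditable rule pipeline for
toxicologists and regulatory scientists, together with the 289-compound
reference dataset on which its predictivity was established.

## The procedure

Each compound is categorized three times against its 2-year tumor outcome:

1. **Histopathology (Step 1).** A compound is subchronic-positive iff the
   study showed cellular **hyperplasia** (or other putative preneoplastic
   change — atypical foci, proliferation, dysplasia). Organ-weight increases
   and cellular **hypertrophy** are adaptive and never count. Crossing the
   screen with the bioassay gives TN / FP / TP / FN.
2. **Pharmacology (Step 2).** Compounds are pooled by primary drug target;
   a class with ≥ 75 % tumor-associated members is called positive, ≤ 25 %
   negative, otherwise mixed. The compound-level category (TP / TN /
   NT / NC) comes from a transcribed class-decision knowledge base, because
   the published decisions fold in literature judgment the fraction cannot
   re-derive (NT = no mammalian target, e.g. antimicrobials; NC =
   non-categorizable).
3. **Combined.** A decisive pharmacological category (TP/TN) overrides
   histopathology; NT/NC fall back to it. Two documented per-compound
   overrides complete the published final column.

Predictivity is summarized per stage by five statistics; for a 2×2 table
with counts TP, FP, FN, TN (indeterminate NT/NC counts join the FP and FN
cells respectively):

- negative predictivity = TN/(TN+FN) × 100
- positive predictivity = TP/(TP+FP) × 100
- sensitivity = TP/(TP+FN) × 100
- specificity = TN/(TN+FP) × 100
- false-negative fraction = FN/N × 100

A final refinement asks, for each false negative, whether every tumor it
induced is of a type regarded as non-predictive for humans (spontaneous
aged-rat tumors: Leydig cell, pheochromocytoma, pituitary, thyroid
follicular, mammary, pancreatic acinar/islet, forestomach, and benign types
generally; see `src/carcwoe/data/relevance.csv`).

## Worked example

```python
>>> import carcwoe as cw
>>> result = cw.run_on_fixture()          # packaged 289-compound dataset
>>> cs = result.summaries["histopathological"]
>>> (cs.tp, cs.fp, cs.fn, cs.tn)
(31, 19, 96, 143)
>>> result.metrics["histopathological"].rounded["negative_predictivity"]
60
>>> fin = result.summaries["final"]
>>> (fin.tp, fin.fp, fin.fn, fin.tn)
(67, 1, 17, 204)
>>> len(result.fn_refinement.not_human_relevant_tumors)
77
```

Reading: histopathology alone predicts non-carcinogens poorly (negative
predictivity 60 %, sensitivity 24 %) because 96 compounds caused tumors with
a clean subchronic study. Folding in class pharmacology resolves most of
them — only 17 false negatives and 1 false positive remain (negative
predictivity 92 %, positive predictivity 98.5 %) — and 77 of the 96 false
negatives induced only tumor types not considered relevant for humans.

The numbered scripts under `analysis/` run the same computations as a
narrative (stage-1 categorization and sub-analyses, class summary,
three-stage metrics table, false-negative refinement, synthetic-data
parameter recovery), writing their tables under `results/`. For example:

```sh
$ python analysis/03_combine_and_metrics.py
final categories: TP 67, FP 1, FN 17, TN 204 (of 289)
negative predictivity 92.3%, positive predictivity 98.53%, sensitivity 79.8%, specificity 99.51%
...
```

## Data and knowledge bases

`src/carcwoe/data/` ships the hand-checked transcription of the published
study table (`compounds.csv`, 289 rows with the published categories as
regression ground truth) and the CSV knowledge bases: organ and morphology
vocabularies, tumor human-relevance rules (with per-rule rationale),
pharmacological class decisions (with the printed class-table placement),
and the two-compound final-category override table. All are plain CSV and
can be extended; the per-compound refinement report
(`results/fn_refinement.csv`) audits every relevance decision so knowledge
bases can be corrected finding by finding.

`carcwoe.simulate` generates synthetic compound datasets with the same
structure (classes, conditional hyperplasia signal, relevant/non-relevant
tumor pools) for property testing and parameter-recovery experiments.

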