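# Methods

## Categorization model

The pipeline is a deterministic rule system over a compound table in a
compact finding grammar (`organ morphology` tokens, `;`-separated;
organ codes may contain an internal space, so a tumor token splits on its
*last* space). Three stages:

**Stage 1 — histopathology.** Subchronic-positive ⇔ the hyperplasia column
is non-empty. This is deliberately restrictive: organ-weight changes and
cellular hypertrophy are treated as adaptive responses, never as
preneoplastic evidence. Foci of cellular alteration, proliferation and
dysplasia are encoded in the hyperplasia column during transcription, since
the reference table collapses them into one column. Crossing with the tumor
outcome (tumor column non-empty) yields TN/FP/TP/FN. The rule is total on
valid records and monotone: adding a hyperplasia finding can only move a
compound toward the subchronic-positive categories.

**Stage 2 — pharmacology.** `class_tumor_fraction` recomputes each class's
tumor fraction from the data and `class_outcome` calls it positive
(fraction ≥ 0.75), negative (≤ 0.25) or mixed. The boundary semantics are
closed on both thresholds because the published positive-class table
contains a 75 % class. Both thresholds are configuration, not constants.
The *compound-level* category, however, is looked up in the transcribed
class-decision table: the published class decisions incorporate mechanism
and literature judgment that no tumor fraction can re-derive
(immunosuppressives are TP with zero observed rat tumors; several
100 %-tumor antimicrobial classes are NT because their primary pharmacology
has no mammalian target). The automatic outcome and the expert decision
are therefore both emitted, and the class summary lists every disagreement
(43 of them on the reference data). Footnoted single-in-class compounds
resolve through compound-specific `single:<id>` rows of the same table.

**Stage 3 — combination.** Pharmacological TP/TN override histopathology;
NT/NC fall back to it. The override table ships with exactly two rows
(compounds 161 → TP and 184 → TN), the only reference rows where the
published final category departs from the closed-form rule; each cites its
narrative justification. On the reference dataset, the recomputed
categories match the published columns 289/289 at all three stages.

## Human-relevance knowledge base

`refine_false_negatives` asks whether *every* tumor of a false-negative
compound belongs to the spectrum of tumor types that occur spontaneously in
aged rats and are regarded as non-predictive for humans. The shipped rule
set (`relevance.csv`) encodes that spectrum in two layers:

- organ rules: pancreatic acinar and islet, adrenal (pheochromocytoma),
  forestomach, thyroid follicular, pituitary adenohypophysis, testis
  (Leydig cell), urinary bladder/urogenital tract, and mammary gland;
  uterine adenocarcinoma as an organ+morphology pair;
- morphology rules: benign entities generally (adenoma, fibroadenoma,
  polyp, papilloma, fibroma, leiomyoma, hemangioma, granulosa cell tumor,
  squamous cell papilloma, benign pheochromocytoma, schwannoma) and the
  spontaneous hematopoietic neoplasms (mononuclear cell leukemia,
  lymphoma).

Matching is by specificity (organ+morphology pair, then organ-only, then
morphology-only), never by file order, and an unmatched tumor type defaults
to human-relevant — the conservative direction for a screen. Hepatocellular
tumors are relevant by default; for compounds flagged as peroxisome
proliferators (the fibrate class) they are treated as non-relevant, since
that exception is mechanism-conditional. Under this rule set 77 of the 96
reference false negatives carry only non-relevant tumor types, and the 19
that remain are exactly the compounds bearing a malignant tumor outside the
spontaneous spectrum (kidney and colon carcinomas, sarcomas, oral squamous
cell carcinoma, hepatocellular carcinoma in non-fibrates, Zymbal gland and
brain malignancies). The refinement report lists, per compound and per
tumor, the rule that fired, so any row can be audited or amended.

Because "move the irrelevant false negatives to TN" admits several
readings, `postfilter_variants` computes three: moving the non-relevant
stage-1 FNs inside the stage-1 table (NPV 92.1 %), moving the non-relevant
compounds among the 17 remaining final FNs (NPV 96.8 %, specificity
99.5 %), and the union with pharmacology-TN FNs (NPV 95.4 %). None is a
regression target; all are reported.

## Metrics

Contingency tables carry six cells. The pharmacological stage places NT in
the positive-prediction/negative-outcome slot and NC in the
negative-prediction/positive-outcome slot, following the published summary
layout, so the five statistics generalize with FP-slot = FP + NT and
FN-slot = FN + NC. Zero denominators produce an explicit `None`, never an
exception, so sweeps over degenerate simulated datasets do not abort. Raw
percentages are always carried beside the rounded presentation values;
default rounding is nearest-integer half-away-from-zero, with floor
available because published tables mix conventions (the reference final
column prints positive predictivity 98 and specificity 99 where the raw
values are 98.53 and 99.51).

One discrepancy is knowingly left standing: the published text counts 99 of
the 143 true negatives as free of any weight/hypertrophy/hyperplasia
finding, while the transcribed table yields 98 (both equal the published
69 %; the per-organ weight and hypertrophy tallies of the transcription
match the published narrative organ-for-organ). The package reports 98.

## Synthetic data generator

`carcwoe.simulate.generate` emulates the categorical structure of the
reference data — nothing mechanistic, no doses or kinetics. Compounds are
grouped into classes (sizes uniform on a configurable range); each compound
is a carcinogen with its class's probability; carcinogens draw 1–3 tumor
types from the human-relevant or non-relevant empirical pool; hyperplasia
appears with probability `hyperplasia_sensitivity` for carcinogens and
`hyperplasia_false_positive_rate` otherwise, sited on a tumor organ with
probability `same_organ_probability`; hypertrophy and weight findings are
independent noise. Defaults are the rates observed in the reference
dataset: prevalence 0.44, sensitivity 0.244, false-positive rate 0.117,
concordance 0.42, non-relevant tumor fraction 0.80, hypertrophy 0.12,
weight findings 0.24. Token pools default to the fixture's observed
vocabulary with empirical frequencies, so generated datasets stress the
same parser and always pass vocabulary validation and write/read
round-trips. A single seeded NumPy generator is threaded through all draws;
a fixed config is bit-reproducible.

What passing simulation tests shows — and what it does not: recovery tests
demonstrate that the pipeline's estimators are unbiased for the generator's
binomial structure (sensitivity/specificity recovered within 3 standard
errors at n = 10⁴, and in mean over 200 replicates at the study's n = 289).
They say nothing about correlated findings within classes, dose dependence,
or reporting variability in real study reports, none of which the generator
models.

## Problem sizes and numerical choices

The reference pipeline is exact integer counting over 289 rows and runs in
well under a second. Simulation suites use 200 replicates at n ≈ 289 plus a
single n = 10⁴ dataset; both complete in a few seconds. Tie-breaking and
degeneracy rules: empty datasets are rejected by the pipeline entry point
(and summarize to all-zero tables with undefined metrics elsewhere);
duplicate finding tokens are preserved on parse and deduplicated only where
an operation is defined on organ sets (concordance); token comparison is
case-insensitive except for the canonical all-caps codes (SCC, SCP, UGT);
variant organ spellings in the source table (`te`/`tes`, `sk`/`skin`,
`thy`/`thym`) are kept as distinct codes rather than silently merged —
concordance compares codes literally, and the vocabulary annotates the
inferred entries (`ce`, `most`) as such.

## Known limitations

- The class-decision and relevance knowledge bases are transcriptions of
  expert judgment; applying the pipeline to new compounds requires
  extending them, and the package can only surface — not resolve —
  disagreements between a class's tumor fraction and its expert decision.
- Single-in-class decisions are per-compound by construction and carry no
  generalization to future members of those classes.
- Dose matching between study pairs, genotoxicity, and mouse data are out
  of scope; the pipeline assumes the compound table already reflects valid
  subchronic/bioassay study pairs.
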