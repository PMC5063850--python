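"""Step 1: categorization from subchronic histopathology.

A compound is subchronic-positive iff it induced putative preneoplastic
lesions — the hyperplasia column only.  Organ-weight changes and cellular
hypertrophy are adaptive responses and never count toward positivity
(compounds inducing hypertrophy only are scored negative).  Crossing that
screen outcome with the 2-year tumor outcome yields TN / FP / TP / FN.

Also here: the descriptive sub-analyses — the no-findings screen (compounds
with completely clean subchronic studies) and organ concordance (did the
hyperplastic lesion and the tumor arise in the same organ?).
"""
from __future__ import annotations

from .dataset import CompoundRecord, Dataset
from .vocab import HISTO_CATEGORIES

__all__ = [
    "categorize_histopathology",
    "histopath_rule",
    "no_findings_screen",
    "organ_concordance",
    "CONCORDANT",
    "DISCORDANT",
    "NOT_APPLICABLE",
]

CONCORDANT = "concordant"
DISCORDANT = "discordant"
NOT_APPLICABLE = "not_applicable"


def categorize_histopathology(rec: CompoundRecord) -> str:
    """Return the stage-1 category (TP/FP/TN/FN) for one compound."""
    sub = rec.subchronic_positive
    carc = rec.carcinogenicity_positive
    if sub:
        return "TP" if carc else "FP"
    return "FN" if carc else "TN"


def histopath_rule(rec: CompoundRecord) -> tuple[str, str]:
    """Category plus a provenance string naming the rule that fired."""
    cat = categorize_histopathology(rec)
    sub = "hyperplasia" if rec.subchronic_positive else "no putative preneoplastic lesion"
    carc = "tumors" if rec.carcinogenicity_positive else "no tumors"
    return cat, f"{sub} + {carc} -> {cat}"


def no_findings_screen(ds: Dataset, within: str) -> list[int]:
    """Ids of compounds in stage-1 category ``within`` whose subchronic study
    was entirely clean (no weight, hypertrophy, or hyperplasia findings)."""
    if within not in HISTO_CATEGORIES:
        raise ValueError(f"unknown category {within!r}; expected one of {HISTO_CATEGORIES}")
    out = []
    for rec in ds:
        if categorize_histopathology(rec) != within:
            continue
        if rec.weight_findings or rec.hypertrophy_findings or rec.hyperplasia_findings:
            continue
        out.append(rec.compound_id)
    return out


def organ_concordance(rec: CompoundRecord) -> str:
    """Did hyperplasia and tumor develop in the same organ?

    Compares deduplicated organ-code sets only (morphology ignored; distinct
    codes such as ``UGT`` vs ``kid`` never match).  Not applicable unless the
    compound has both hyperplasia and tumor findings.
    """
    if not rec.hyperplasia_findings or not rec.tumor_findings:
        return NOT_APPLICABLE
    hp_organs = {f.organ for f in rec.hyperplasia_findings}
    tumor_organs = {f.organ for f in rec.tumor_findings}
    return CONCORDANT if hp_organs & tumor_organs else DISCORDANT
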