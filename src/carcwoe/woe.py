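"""Final weight-of-evidence categorization and false-negative refinement.

The combine rule: a decisive pharmacological category (TP or TN) overrides
the histopathological one; an indecisive category (NT — no mammalian
target, NC — non-categorizable) falls back to histopathology.  A small
override table captures the two published per-compound departures from this
rule, each citing its narrative justification.

The refinement step asks, for each histopathological false negative,
whether *every* tumor it induced is of a type considered non-predictive for
humans (spontaneous aged-rat tumor types; see the relevance knowledge
base).  Compounds flagged for peroxisome proliferation additionally treat
hepatocellular tumors as non-relevant, since that exception is
mechanism-conditional.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .dataset import Dataset, Finding
from .vocab import (
    HISTO_CATEGORIES,
    PHARM_CATEGORIES,
    OverrideRule,
    TumorRelevanceRule,
    is_human_relevant,
    matching_relevance_rule,
)

__all__ = [
    "combine_final",
    "refine_false_negatives",
    "postfilter_variants",
    "FNRefinement",
    "FNRefinementRow",
]

_LIVER_TUMOR_MORPHOLOGIES = {"ad", "ac", "ca", "tu"}


def combine_final(
    cat_his: str,
    cat_ph: str,
    compound_id: int,
    overrides: Mapping[int, OverrideRule] | None = None,
) -> tuple[str, str]:
    """Final category plus provenance for one compound."""
    if cat_his not in HISTO_CATEGORIES:
        raise ValueError(f"invalid histopathological category {cat_his!r}")
    if cat_ph not in PHARM_CATEGORIES:
        raise ValueError(f"invalid pharmacological category {cat_ph!r}")
    if overrides and compound_id in overrides:
        rule = overrides[compound_id]
        return rule.forced_final, f"override: {rule.rationale or 'per-compound override'}"
    if cat_ph in ("TP", "TN"):
        return cat_ph, f"pharmacology decisive ({cat_ph})"
    return cat_his, f"pharmacology {cat_ph} -> histopathology {cat_his}"


def _finding_not_relevant(
    finding: Finding,
    rules: Sequence[TumorRelevanceRule],
    peroxisome_proliferator: bool,
) -> tuple[bool, str]:
    """(is the tumor non-relevant?, which rule/mechanism said so)."""
    if (
        peroxisome_proliferator
        and finding.organ == "li"
        and finding.morphology in _LIVER_TUMOR_MORPHOLOGIES
    ):
        return True, "hepatocellular tumor of a peroxisome proliferator"
    if not is_human_relevant(finding, rules):
        rule = matching_relevance_rule(finding, rules)
        label = rule.rationale if rule and rule.rationale else f"rule {rule.organ}/{rule.morphology}" if rule else ""
        return True, label
    return False, ""


@dataclass
class FNRefinementRow:
    compound_id: int
    tumors: tuple[Finding, ...]
    human_relevant: bool
    detail: list[str] = field(default_factory=list)  # per-tumor matched rule or "relevant"


@dataclass
class FNRefinement:
    human_relevant_tumors: list[int] = field(default_factory=list)
    not_human_relevant_tumors: list[int] = field(default_factory=list)
    rows: list[FNRefinementRow] = field(default_factory=list)

    @property
    def n_fn(self) -> int:
        return len(self.human_relevant_tumors) + len(self.not_human_relevant_tumors)


def postfilter_variants(
    cat_his: Mapping[int, str],
    cat_ph: Mapping[int, str],
    cat_final: Mapping[int, str],
    refinement: FNRefinement,
):
    """Predictivity after moving human-irrelevant false negatives to TN.

    Exactly which set of compounds is moved is a genuine reading choice, so
    three variants are computed side by side:

    ``histopath_fns_moved``
        stage-1 table, the non-relevant stage-1 FNs recounted as TN;
    ``final_fns_moved``
        final table, the non-relevant compounds among the remaining final
        FNs recounted as TN;
    ``union_pharm_tn``
        stage-1 table, FNs that are non-relevant *or* pharmacologically TN
        recounted as TN.

    Returns ``{variant: (ContingencySummary, PredictivityMetrics)}``.
    """
    from .metrics import compute_metrics, summarize  # avoid import cycle at module load

    nonrel = set(refinement.not_human_relevant_tumors)
    pharm_tn = {cid for cid, cat in cat_ph.items() if cat == "TN"}

    def moved(base: Mapping[int, str], move: set[int], stage: str):
        cats = {
            cid: ("TN" if cat == "FN" and cid in move else cat)
            for cid, cat in base.items()
        }
        cs = summarize(cats, stage)
        return cs, compute_metrics(cs)

    return {
        "histopath_fns_moved": moved(cat_his, nonrel, "histopathological"),
        "final_fns_moved": moved(cat_final, nonrel, "final"),
        "union_pharm_tn": moved(cat_his, nonrel | pharm_tn, "histopathological"),
    }


def refine_false_negatives(
    ds: Dataset,
    cat_his: Mapping[int, str],
    rules: Sequence[TumorRelevanceRule],
) -> FNRefinement:
    """Partition the histopathological FN compounds by tumor relevance.

    A compound lands in ``not_human_relevant_tumors`` iff every one of its
    tumor findings is of a non-relevant type; a single relevant tumor keeps
    it in ``human_relevant_tumors``.  The per-compound rows record which
    rule matched each tumor, so disagreements with published counts can be
    audited finding by finding.
    """
    result = FNRefinement()
    for rec in ds:
        if cat_his.get(rec.compound_id) != "FN":
            continue
        detail: list[str] = []
        any_relevant = False
        for finding in rec.tumor_findings:
            not_rel, why = _finding_not_relevant(
                finding, rules, rec.peroxisome_proliferator
            )
            if not_rel:
                detail.append(f"{finding}: not relevant ({why})")
            else:
                any_relevant = True
                detail.append(f"{finding}: human-relevant (no rule matched)")
        row = FNRefinementRow(
            compound_id=rec.compound_id,
            tumors=rec.tumor_findings,
            human_relevant=any_relevant,
            detail=detail,
        )
        result.rows.append(row)
        if any_relevant:
            result.human_relevant_tumors.append(rec.compound_id)
        else:
            result.not_human_relevant_tumors.append(rec.compound_id)
    return result
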