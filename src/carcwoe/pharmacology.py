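"""Step 2: categorization from pharmacological class knowledge.

Compounds sharing a primary pharmacological target are pooled; the fraction
of class members associated with tumors in the 2-year study calls the class
positive (>= 75%), negative (<= 25%) or mixed.  The compound-level category,
however, comes from the transcribed class-decision knowledge base, because
the published class decisions fold in literature judgment that no tumor
fraction can re-derive (immunosuppressives are called TP with zero rat
tumors; several 100%-tumor classes are NT because their target is
non-mammalian).  Both the automatic outcome and the expert decision are
computed so disagreements stay visible.

Single-in-class compounds (the footnoted rows of the reference table) carry
a compound-specific decision keyed ``single:<id>`` in the same table.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

from .dataset import CompoundRecord, Dataset
from .vocab import ClassDecision

__all__ = [
    "ClassOutcomeConfig",
    "ClassTumorFraction",
    "UnknownClassError",
    "UnassignedClassError",
    "class_tumor_fraction",
    "class_outcome",
    "assign_pharm_category",
    "single_key",
]

POSITIVE = "positive"
NEGATIVE = "negative"
MIXED = "mixed"


class UnknownClassError(KeyError):
    def __str__(self) -> str:
        return f"unknown pharmacological class {self.args[0]!r}"


class UnassignedClassError(KeyError):
    """Compound's class has no decision and the compound is not single-in-class."""

    def __str__(self) -> str:
        return (
            f"no class decision for {self.args[0]!r}; add it to the "
            "class-decision knowledge base or flag the compound single-in-class"
        )


@dataclass(frozen=True)
class ClassOutcomeConfig:
    """Thresholds for calling a class from its tumor fraction.

    Defaults follow the published criteria: at least 75% of members
    tumor-associated -> positive class, at most 25% -> negative, otherwise
    mixed.  Kept configurable so threshold sensitivity can be explored.
    """

    positive_threshold: float = 0.75
    negative_threshold: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.negative_threshold < self.positive_threshold <= 1:
            raise ValueError(
                "thresholds must satisfy 0 < negative < positive <= 1, got "
                f"{self.negative_threshold}/{self.positive_threshold}"
            )


class ClassTumorFraction(NamedTuple):
    n_members: int
    n_with_tumors: int
    fraction: float


def class_tumor_fraction(ds: Dataset, class_id: str) -> ClassTumorFraction:
    """Members of a class, how many were tumor-associated, and the fraction."""
    members = [rec for rec in ds if rec.pharm_class_id == class_id]
    if not members:
        raise UnknownClassError(class_id)
    n_tum = sum(rec.carcinogenicity_positive for rec in members)
    return ClassTumorFraction(len(members), n_tum, n_tum / len(members))


def class_outcome(fraction: float, cfg: ClassOutcomeConfig | None = None) -> str:
    """Call a class positive / negative / mixed from its tumor fraction."""
    cfg = cfg or ClassOutcomeConfig()
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    if fraction >= cfg.positive_threshold:
        return POSITIVE
    if fraction <= cfg.negative_threshold:
        return NEGATIVE
    return MIXED


def single_key(compound_id: int) -> str:
    return f"single:{compound_id}"


def assign_pharm_category(
    rec: CompoundRecord, decisions: Mapping[str, ClassDecision]
) -> tuple[str, str]:
    """Pharmacological category (TP/TN/NT/NC) plus provenance.

    Single-in-class compounds resolve to their compound-specific decision;
    everything else to its class's decision.  A missing decision raises
    :class:`UnassignedClassError` naming the class.
    """
    if rec.single_in_class:
        key = single_key(rec.compound_id)
        decision = decisions.get(key)
        if decision is None:
            raise UnassignedClassError(key)
        return decision.decision, f"single-in-class decision {key}"
    decision = decisions.get(rec.pharm_class_id)
    if decision is None:
        raise UnassignedClassError(rec.pharm_class_id)
    return decision.decision, f"class decision {rec.pharm_class_id!r} ({decision.table_of_origin} table)"
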