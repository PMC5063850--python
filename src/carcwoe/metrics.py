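"""Contingency summaries and predictivity statistics.

Five statistics describe how well a categorization stage predicts the
2-year bioassay outcome:

====================  =====================================
false-negative rate   FN / N x 100
negative predictivity TN / (TN + FN) x 100
positive predictivity TP / (TP + FP) x 100
sensitivity           TP / (TP + FN) x 100
specificity           TN / (TN + FP) x 100
====================  =====================================

The pharmacological stage has two extra cells: NT (no mammalian target)
compounds sit in the positive-prediction/negative-outcome (FP) slot and NC
(non-categorizable) in the negative-prediction/positive-outcome (FN) slot,
mirroring the published summary layout, so the five statistics generalize
with FP-slot = FP + NT and FN-slot = FN + NC.

Zero denominators yield ``None`` (an explicit undefined marker), never an
exception, so parameter sweeps over degenerate datasets do not abort.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "ContingencySummary",
    "PredictivityMetrics",
    "summarize",
    "compute_metrics",
    "round_half_away",
]

STAGES = ("histopathological", "pharmacological", "final")

_METRIC_NAMES = (
    "fn_fraction",
    "negative_predictivity",
    "positive_predictivity",
    "sensitivity",
    "specificity",
)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ContingencySummary:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    nt: int = 0
    nc: int = 0
    stage: str = "histopathological"

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn", "nt", "nc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count is negative")
        if self.stage not in STAGES:
            raise ValueError(f"stage {self.stage!r} not in {STAGES}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn + self.nt + self.nc

    @property
    def fp_slot(self) -> int:
        """Positive-prediction/negative-outcome cell (FP plus NT)."""
        return self.fp + self.nt

    @property
    def fn_slot(self) -> int:
        """Negative-prediction/positive-outcome cell (FN plus NC)."""
        return self.fn + self.nc


def summarize(categories: Mapping[int, str] | Iterable[str], stage: str) -> ContingencySummary:
    """Count categories into a contingency summary for one stage.

    ``categories`` maps compound id -> category (or is a plain iterable of
    category values).  For the pharmacological stage the NT and NC counts
    occupy their own cells; for the other stages only TP/FP/FN/TN may occur.
    """
    if stage not in STAGES:
        raise ValueError(f"stage {stage!r} not in {STAGES}")
    values = categories.values() if isinstance(categories, Mapping) else categories
    counts = {"TP": 0, "FP": 0, "FN": 0, "TN": 0, "NT": 0, "NC": 0}
    for cat in values:
        if cat not in counts:
            raise ValueError(f"invalid category {cat!r}")
        counts[cat] += 1
    if stage != "pharmacological" and (counts["NT"] or counts["NC"]):
        raise ValueError(f"NT/NC categories are only valid in the pharmacological stage")
    return ContingencySummary(
        tp=counts["TP"],
        fp=counts["FP"],
        fn=counts["FN"],
        tn=counts["TN"],
        nt=counts["NT"],
        nc=counts["NC"],
        stage=stage,
    )


@dataclass(frozen=True)
class PredictivityMetrics:
    """Raw (unrounded) percentages plus their rounded presentation values.

    A metric whose denominator is zero is ``None`` in both forms.
    """

    fn_fraction: float | None
    negative_predictivity: float | None
    positive_predictivity: float | None
    sensitivity: float | None
    specificity: float | None
    rounded: dict[str, int | None]

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in _METRIC_NAMES}


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(
    cs: ContingencySummary, rounding: str = "half_away"
) -> PredictivityMetrics:
    """The five predictivity statistics for a contingency summary.

    ``rounding`` is ``"half_away"`` (default) or ``"floor"``; raw values are
    always carried alongside, since published tables do not always follow a
    single rounding convention.
    """
    raw = {
        "fn_fraction": _pct(cs.fn_slot, cs.total),
        "negative_predictivity": _pct(cs.tn, cs.tn + cs.fn_slot),
        "positive_predictivity": _pct(cs.tp, cs.tp + cs.fp_slot),
        "sensitivity": _pct(cs.tp, cs.tp + cs.fn_slot),
        "specificity": _pct(cs.tn, cs.tn + cs.fp_slot),
    }
    if rounding == "half_away":
        rounder = round_half_away
    elif rounding == "floor":
        rounder = lambda x: int(math.floor(x))
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    rounded = {k: (None if v is None else rounder(v)) for k, v in raw.items()}
    return PredictivityMetrics(rounded=rounded, **raw)
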