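"""End-to-end pipeline: histopathology, pharmacology, combined category,
metrics, class summary, and false-negative refinement in one call.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .dataset import Dataset, load_fixture, read_dataset
from .histopath import histopath_rule, organ_concordance
from .metrics import ContingencySummary, PredictivityMetrics, compute_metrics, summarize
from .pharmacology import (
    ClassOutcomeConfig,
    assign_pharm_category,
    class_outcome,
    class_tumor_fraction,
)
from .vocab import (
    ClassDecision,
    OverrideRule,
    TumorRelevanceRule,
    Vocabulary,
    load_class_decisions,
    load_default_class_decisions,
    load_default_overrides,
    load_default_relevance_rules,
    load_default_vocabulary,
    load_overrides,
    load_relevance_rules,
    load_vocabulary,
)
from .woe import FNRefinement, combine_final, refine_false_negatives

__all__ = [
    "CategoryAssignment",
    "KnowledgeBase",
    "PipelineResult",
    "load_default_kb",
    "load_kb",
    "run_pipeline",
]


@dataclass(frozen=True)
class CategoryAssignment:
    """All three categories for one compound, with rule provenance."""

    compound_id: int
    cat_his: str
    cat_ph: str
    cat_final: str
    fired_his: str
    fired_ph: str
    fired_final: str
    concordance: str


@dataclass
class KnowledgeBase:
    vocab: Vocabulary
    relevance_rules: list[TumorRelevanceRule]
    class_decisions: dict[str, ClassDecision]
    overrides: dict[int, OverrideRule]


def load_default_kb() -> KnowledgeBase:
    """The packaged knowledge bases (vocabulary, relevance, class decisions,
    overrides) transcribed from the published study."""
    return KnowledgeBase(
        vocab=load_default_vocabulary(),
        relevance_rules=load_default_relevance_rules(),
        class_decisions=load_default_class_decisions(),
        overrides=load_default_overrides(),
    )


def load_kb(directory: Path | str) -> KnowledgeBase:
    """Load a knowledge-base directory holding organs.csv, morphologies.csv,
    relevance.csv, class_decisions.csv and overrides.csv."""
    d = Path(directory)
    return KnowledgeBase(
        vocab=load_vocabulary(d / "organs.csv", d / "morphologies.csv"),
        relevance_rules=load_relevance_rules(d / "relevance.csv"),
        class_decisions=load_class_decisions(d / "class_decisions.csv"),
        overrides=load_overrides(d / "overrides.csv"),
    )


@dataclass
class ClassSummaryRow:
    class_id: str
    n_members: int
    n_with_tumors: int
    fraction: float
    automatic_outcome: str
    decision: str
    table_of_origin: str


@dataclass
class PipelineResult:
    dataset: Dataset
    assignments: list[CategoryAssignment]
    summaries: dict[str, ContingencySummary]
    metrics: dict[str, PredictivityMetrics]
    class_summary: list[ClassSummaryRow]
    fn_refinement: FNRefinement

    def categories(self, stage: str) -> dict[int, str]:
        attr = {"histopathological": "cat_his", "pharmacological": "cat_ph", "final": "cat_final"}[stage]
        return {a.compound_id: getattr(a, attr) for a in self.assignments}


def run_pipeline(
    ds: Dataset | Path | str,
    kb: KnowledgeBase | None = None,
    outcome_cfg: ClassOutcomeConfig | None = None,
) -> PipelineResult:
    """Run the full weight-of-evidence categorization.

    ``ds`` may be a loaded dataset or a path to a compounds CSV (validated
    against the knowledge base's vocabulary).  Returns per-compound
    assignments with provenance, the three-stage contingency summaries and
    predictivity metrics, the class summary (recomputed tumor fractions and
    automatic outcomes side by side with the transcribed decisions), and the
    false-negative relevance refinement.
    """
    kb = kb or load_default_kb()
    if not isinstance(ds, Dataset):
        ds = read_dataset(ds, kb.vocab)
    if not len(ds):
        raise ValueError("dataset is empty; nothing to categorize")

    assignments: list[CategoryAssignment] = []
    for rec in ds:
        cat_his, fired_his = histopath_rule(rec)
        cat_ph, fired_ph = assign_pharm_category(rec, kb.class_decisions)
        cat_final, fired_final = combine_final(
            cat_his, cat_ph, rec.compound_id, kb.overrides
        )
        assignments.append(
            CategoryAssignment(
                compound_id=rec.compound_id,
                cat_his=cat_his,
                cat_ph=cat_ph,
                cat_final=cat_final,
                fired_his=fired_his,
                fired_ph=fired_ph,
                fired_final=fired_final,
                concordance=organ_concordance(rec),
            )
        )

    his = {a.compound_id: a.cat_his for a in assignments}
    ph = {a.compound_id: a.cat_ph for a in assignments}
    fin = {a.compound_id: a.cat_final for a in assignments}
    summaries = {
        "histopathological": summarize(his, "histopathological"),
        "pharmacological": summarize(ph, "pharmacological"),
        "final": summarize(fin, "final"),
    }
    metrics = {stage: compute_metrics(cs) for stage, cs in summaries.items()}

    class_summary = []
    for class_id in ds.class_ids():
        n, n_tum, frac = class_tumor_fraction(ds, class_id)
        decision = kb.class_decisions.get(class_id)
        class_summary.append(
            ClassSummaryRow(
                class_id=class_id,
                n_members=n,
                n_with_tumors=n_tum,
                fraction=frac,
                automatic_outcome=class_outcome(frac, outcome_cfg),
                decision=decision.decision if decision else "",
                table_of_origin=decision.table_of_origin if decision else "",
            )
        )

    fn_refinement = refine_false_negatives(ds, his, kb.relevance_rules)
    return PipelineResult(
        dataset=ds,
        assignments=assignments,
        summaries=summaries,
        metrics=metrics,
        class_summary=class_summary,
        fn_refinement=fn_refinement,
    )


def run_on_fixture(kb: KnowledgeBase | None = None) -> PipelineResult:
    """Convenience: run the pipeline on the packaged reference dataset."""
    kb = kb or load_default_kb()
    return run_pipeline(load_fixture(kb.vocab), kb)
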