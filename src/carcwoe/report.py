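"""Human-readable report writers: per-compound assignments, the three-stage
predictivity table, the class summary, and the false-negative refinement
report.  All outputs are deterministic delimited text or markdown."""
from __future__ import annotations

import csv
from pathlib import Path

from .metrics import ContingencySummary, PredictivityMetrics
from .pipeline import PipelineResult

__all__ = [
    "write_assignments",
    "write_class_summary",
    "write_metrics_table",
    "write_refinement_report",
    "metrics_markdown",
    "write_report_bundle",
]

_METRIC_LABELS = [
    ("fn_fraction", "False negatives (%)"),
    ("negative_predictivity", "Negative predictivity (%)"),
    ("positive_predictivity", "Positive predictivity (%)"),
    ("sensitivity", "Sensitivity (%)"),
    ("specificity", "Specificity (%)"),
]


def write_assignments(result: PipelineResult, path: Path | str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["compound_id", "cat_his", "cat_ph", "cat_final",
             "organ_concordance", "fired_his", "fired_ph", "fired_final"]
        )
        for a in result.assignments:
            w.writerow(
                [a.compound_id, a.cat_his, a.cat_ph, a.cat_final,
                 a.concordance, a.fired_his, a.fired_ph, a.fired_final]
            )


def write_class_summary(result: PipelineResult, path: Path | str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["class_id", "n_members", "n_with_tumors", "tumor_fraction",
             "automatic_outcome", "decision", "table_of_origin"]
        )
        for row in sorted(result.class_summary, key=lambda r: r.class_id):
            w.writerow(
                [row.class_id, row.n_members, row.n_with_tumors,
                 f"{row.fraction:.3f}", row.automatic_outcome, row.decision,
                 row.table_of_origin]
            )


def _fmt(value: float | None, digits: int = 1) -> str:
    return "undef" if value is None else f"{value:.{digits}f}"


def metrics_markdown(result: PipelineResult) -> str:
    """Markdown table mirroring the three-stage predictivity layout."""
    stages = ["histopathological", "pharmacological", "final"]
    lines = [
        "| | " + " | ".join(s.capitalize() for s in stages) + " |",
        "|---|---|---|---|",
    ]
    cells = []
    for s in stages:
        cs = result.summaries[s]
        pos_neg = f"{cs.fp}" + (f" + {cs.nt} (NT)" if cs.nt else "")
        neg_pos = f"{cs.fn}" + (f" + {cs.nc} (NC)" if cs.nc else "")
        cells.append((f"{cs.tp} / {pos_neg}", f"{neg_pos} / {cs.tn}"))
    lines.append("| Subchronic positive: TP / FP-slot | "
                 + " | ".join(c[0] for c in cells) + " |")
    lines.append("| Subchronic negative: FN-slot / TN | "
                 + " | ".join(c[1] for c in cells) + " |")
    for key, label in _METRIC_LABELS:
        row = [label]
        for s in stages:
            m = result.metrics[s]
            raw = getattr(m, key)
            rounded = m.rounded[key]
            row.append("undef" if raw is None else f"{rounded} ({raw:.1f})")
        lines.append("| " + " | ".join(row) + " |")
    return "\n".join(lines) + "\n"


def write_metrics_table(result: PipelineResult, path: Path | str) -> None:
    """CSV with raw and rounded metric values for all three stages."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["stage", "tp", "fp", "fn", "tn", "nt", "nc", "metric", "raw", "rounded"])
        for stage, cs in result.summaries.items():
            m = result.metrics[stage]
            for key, _ in _METRIC_LABELS:
                raw = getattr(m, key)
                w.writerow(
                    [stage, cs.tp, cs.fp, cs.fn, cs.tn, cs.nt, cs.nc, key,
                     "" if raw is None else f"{raw:.4f}",
                     "" if m.rounded[key] is None else m.rounded[key]]
                )


def write_refinement_report(result: PipelineResult, path: Path | str) -> None:
    """Per-FN-compound relevance audit: every tumor and the rule it matched."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "bucket", "tumors", "detail"])
        for row in sorted(result.fn_refinement.rows, key=lambda r: r.compound_id):
            bucket = "human_relevant" if row.human_relevant else "not_human_relevant"
            tumors = "; ".join(str(t) for t in row.tumors)
            w.writerow([row.compound_id, bucket, tumors, " | ".join(row.detail)])


def write_report_bundle(result: PipelineResult, directory: Path | str) -> dict[str, Path]:
    """Write the full report bundle into a directory; returns the paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "assignments": d / "assignments.csv",
        "class_summary": d / "class_summary.csv",
        "metrics": d / "metrics.csv",
        "fn_refinement": d / "fn_refinement.csv",
        "metrics_markdown": d / "metrics.md",
    }
    write_assignments(result, paths["assignments"])
    write_class_summary(result, paths["class_summary"])
    write_metrics_table(result, paths["metrics"])
    write_refinement_report(result, paths["fn_refinement"])
    paths["metrics_markdown"].write_text(metrics_markdown(result), encoding="utf-8")
    return paths
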