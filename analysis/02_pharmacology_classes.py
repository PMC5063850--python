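#!/usr/bin/env python
"""Stage 2: tumor fractions per pharmacological class, the automatic
positive/negative/mixed outcome at the 75%/25% thresholds, and the expert
class decisions used for compound-level categorization.

Writes results/class_summary.csv and prints the classes where the automatic
outcome and the expert decision disagree — the cases where literature
judgment overrode the raw tumor fraction.
"""
from pathlib import Path

from carcwoe.pipeline import run_on_fixture
from carcwoe.report import write_class_summary

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    result = run_on_fixture()
    cs = result.summaries["pharmacological"]
    print(
        f"pharmacological categories over {cs.total} compounds: "
        f"TP {cs.tp}, TN {cs.tn}, NT {cs.nt} (no mammalian target), "
        f"NC {cs.nc} (non-categorizable)"
    )

    auto_to_cat = {"positive": "TP", "negative": "TN"}
    disagreements = [
        row
        for row in result.class_summary
        if not row.class_id.startswith("single:")
        and row.decision
        and auto_to_cat.get(row.automatic_outcome) != row.decision
    ]
    print(f"\n{len(disagreements)} classes where the expert decision departs "
          "from the raw tumor-fraction outcome, e.g.:")
    for row in sorted(disagreements, key=lambda r: r.class_id)[:12]:
        print(
            f"  {row.class_id}: {row.n_with_tumors}/{row.n_members} tumors "
            f"({row.automatic_outcome}) -> decision {row.decision}"
        )

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "class_summary.csv"
    write_class_summary(result, out)
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
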