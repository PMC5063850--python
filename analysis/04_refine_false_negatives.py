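#!/usr/bin/env python
"""Human-relevance refinement of the false negatives.

Partitions the 96 stage-1 false negatives by whether every tumor they
induced is of a type considered non-predictive for humans, then recomputes
the predictivity under the three defensible readings of "move the
irrelevant FNs to TN".  Writes results/fn_postfilter_variants.csv (the
per-compound audit is already in results/fn_refinement.csv from script 03).
"""
import csv
from pathlib import Path

from carcwoe.pipeline import run_on_fixture
from carcwoe.report import write_refinement_report
from carcwoe.woe import postfilter_variants

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    result = run_on_fixture()
    ref = result.fn_refinement
    print(
        f"{len(ref.not_human_relevant_tumors)} of {ref.n_fn} false negatives "
        f"({100 * len(ref.not_human_relevant_tumors) / ref.n_fn:.0f}%) induced "
        "only tumor types considered not relevant for humans."
    )
    print(
        "still bearing a human-relevant tumor: "
        f"{sorted(ref.human_relevant_tumors)}"
    )

    variants = postfilter_variants(
        result.categories("histopathological"),
        result.categories("pharmacological"),
        result.categories("final"),
        ref,
    )
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "fn_postfilter_variants.csv"
    with open(out, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["variant", "tp", "fp", "fn", "tn",
                    "negative_predictivity", "specificity"])
        for name, (cs, m) in variants.items():
            w.writerow([name, cs.tp, cs.fp, cs.fn, cs.tn,
                        f"{m.negative_predictivity:.2f}", f"{m.specificity:.2f}"])
            print(
                f"  {name}: FN {cs.fn}, TN {cs.tn} -> "
                f"NPV {m.negative_predictivity:.1f}%, "
                f"specificity {m.specificity:.1f}%"
            )
    write_refinement_report(result, RESULTS / "fn_refinement.csv")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
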