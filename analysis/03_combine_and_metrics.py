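#!/usr/bin/env python
"""Combined weight-of-evidence categorization and the three-stage
predictivity table.

Writes the full report bundle (assignments, metrics, class summary,
FN-refinement audit) under results/ and prints the predictivity table in
the three-stage layout.
"""
from pathlib import Path

from carcwoe.pipeline import run_on_fixture
from carcwoe.report import metrics_markdown, write_report_bundle

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    result = run_on_fixture()
    fin = result.summaries["final"]
    print(
        f"final categories: TP {fin.tp}, FP {fin.fp}, FN {fin.fn}, TN {fin.tn} "
        f"(of {fin.total})"
    )
    m = result.metrics["final"]
    print(
        f"negative predictivity {m.negative_predictivity:.1f}%, "
        f"positive predictivity {m.positive_predictivity:.2f}%, "
        f"sensitivity {m.sensitivity:.1f}%, specificity {m.specificity:.2f}%"
    )
    print("\n" + metrics_markdown(result))
    paths = write_report_bundle(result, RESULTS)
    print("wrote " + ", ".join(str(p) for p in paths.values()))


if __name__ == "__main__":
    main()
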