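#!/usr/bin/env python
"""Audit documentation completeness on the simulated cohort and compare
with the published per-parameter rates.

Generalizable parameters are audited against the whole cohort; patient-
specific ones against their intraoperative occurrence counts, so rates
above 100% flag radiologist over-calling.  Writes rates.csv and
summary.json, and prints the simulated vs published rates side by side
together with the category medians.
"""

import argparse
import json
from pathlib import Path

from stampc import reference
from stampc.audit import audit_rates, format_pct, rates_from_counts, summarize
from stampc.dataset import read_registry_csv, read_reports_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/audit"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    registry = read_registry_csv(args.data_dir / "registry.csv")
    reports = read_reports_csv(args.data_dir / "reports.csv")
    rates = audit_rates(reports, registry)
    published = {
        r.parameter_id: r
        for r in rates_from_counts(
            reference.DOCUMENTED_COUNTS, reference.OCCURRENCE_COUNTS, reference.COHORT_N
        )
    }

    with open(args.out_dir / "rates.csv", "w", encoding="utf-8") as fh:
        fh.write("parameter,category,numerator,denominator,rate_pct,published_pct\n")
        for r in rates:
            fh.write(
                f"{r.parameter_id},{r.category.value},{r.numerator},"
                f"{r.denominator},{format_pct(r.rate_pct)},"
                f"{format_pct(published[r.parameter_id].rate_pct)}\n"
            )

    print(f"{'parameter':26s} {'simulated':>10s} {'published':>10s}")
    for r in rates:
        print(
            f"{r.parameter_id:26s} {r.rate_pct:9.1f}% "
            f"{published[r.parameter_id].rate_pct:9.1f}%"
        )

    summaries = summarize(rates)
    payload = {
        scope: {"median_pct": s.median_pct, "min_pct": s.min_pct, "max_pct": s.max_pct}
        for scope, s in summaries.items()
    }
    (args.out_dir / "summary.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(
        "\nmedians (simulated): "
        f"generalizable {summaries['generalizable'].median_pct:.1f}% "
        "(published 24.2%), "
        f"patient-specific {summaries['patient_specific'].median_pct:.1f}% "
        "(published 87.8%), "
        f"overall pooled {summaries['overall'].median_pct:.1f}%"
    )
    print(
        "note: the pooled midpoint median of the 16 published rates is 32.0; "
        "the published overall headline (34.4) corresponds to the midpoint "
        "of the 9th/10th order statistics"
    )


if __name__ == "__main__":
    main()
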