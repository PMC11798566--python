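#!/usr/bin/env python
"""Sensitivity analysis: drop the two highest ambient-light participants.

Re-runs the group comparison after excluding the two participants with the
highest mean session-level ambient-light SD, to check that the ambient-light
group difference is not driven by those individuals.
"""

import argparse
import sys
from pathlib import Path

from digiphen.features import Feature, read_feature_table
from digiphen.outliers import exclude_participants, top_participants_by_feature
from digiphen.pipeline import PipelineConfig, analyze, clean_features
from digiphen.stats import build_report, format_report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--features", type=Path, default=ROOT / "scratch" / "features_raw.csv")
    args = parser.parse_args()

    cfg = PipelineConfig()
    retained, _, _ = clean_features(read_feature_table(args.features), cfg)
    excluded = top_participants_by_feature(retained, Feature.AMBIENT_LIGHT_SD, k=2)
    print(f"excluding participants with highest ambient-light SD: {excluded}")

    results, _ = analyze(exclude_participants(retained, excluded), cfg)
    report = build_report(results)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    report.to_csv(out / "group_comparison_sensitivity.csv", index=False)
    (out / "group_comparison_sensitivity.txt").write_text(format_report(report))

    row = report[report["feature"] == int(Feature.AMBIENT_LIGHT_SD)].iloc[0]
    print(format_report(report))
    print(f"ambient-light group difference after exclusion: "
          f"P={row['p_value']:.3f} ({'still ' if row['significant'] else 'no longer '}significant)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
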