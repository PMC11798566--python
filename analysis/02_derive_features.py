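#!/usr/bin/env python
"""Derive the ten digital-phenotype features from the raw streams.

Reads scratch/cohort/, runs sessionization, notification matching, sleep
exclusion and all feature aggregations. The full long-format observation
table goes to scratch/ (it has ~10^5 rows); a per-feature group summary of
means/SDs goes to results/feature_summary.csv.
"""

import argparse
import sys
from pathlib import Path

from digiphen.features import FEATURE_NAMES, Feature, write_feature_table
from digiphen.pipeline import extract_features
from digiphen.simulate import load_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=ROOT / "scratch" / "cohort")
    args = parser.parse_args()

    cohort = load_cohort(args.cohort)
    frame, counts, sessions = extract_features(cohort)
    write_feature_table(frame, ROOT / "scratch" / "features_raw.csv")

    summary = (
        frame.groupby(["feature_id", "group"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    summary["feature"] = summary["feature_id"].map(lambda f: FEATURE_NAMES[Feature(f)])
    out = ROOT / "results" / "feature_summary.csv"
    out.parent.mkdir(exist_ok=True)
    summary.to_csv(out, index=False)

    print(f"{len(frame):,} feature observations from {counts['sessions_total']:,} sessions")
    print(f"notifications: {counts['notifications_total']:,} total, "
          f"{counts['notifications_sleep_excluded']:,} during sleep, "
          f"{counts['notifications_matched']:,} matched to an unlock")
    print(f"group summary written to {out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
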