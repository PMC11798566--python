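#!/usr/bin/env python
"""Generate the synthetic study cohort.

Writes raw event streams for 20 ADHD + 20 comparison participants over 10
weeks of 24/7 monitoring to scratch/cohort/ (large intermediates live under
scratch/, not results/). The streams encode the published group feature
distributions, so the downstream scripts can recover them.
"""

import argparse
import sys
from pathlib import Path

from digiphen.simulate import CohortConfig, generate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=ROOT / "scratch" / "cohort")
    args = parser.parse_args()

    cfg = CohortConfig(seed=args.seed)
    cohort = generate_cohort(cfg, out_dir=args.out, overwrite=True)
    n_events = sum(
        len(ps.phone_status) + len(ps.app_events) + len(ps.light) + len(ps.steps)
        for ps in cohort.streams.values()
    )
    print(f"cohort: {len(cohort.streams)} participants ({cfg.n_per_group} per group), "
          f"{cfg.weeks} weeks, seed {cfg.seed}")
    print(f"{n_events:,} raw events written to {args.out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
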