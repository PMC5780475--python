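#!/usr/bin/env python
"""Validate histogram-class volumetry against phantom ground truth.

Runs the full quantification chain (segmentation → histogram → Gaussian
classes → inflection boundaries → volumes) on 20 phantoms whose cortex
share spans 60–80% and compares the recovered compartment fractions with
the exact label counts. Writes per-phantom errors to
``results/fraction_recovery.csv``; the pipeline is considered sound when
the mean absolute error stays below 2 percentage points.
"""

import argparse
from pathlib import Path

import pandas as pd

from renalvh.studies import fraction_recovery_study

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=101)
    ap.add_argument("--n-phantoms", type=int, default=20)
    args = ap.parse_args()

    res = fraction_recovery_study(n_phantoms=args.n_phantoms, seed=args.seed)
    df = pd.DataFrame(res["per_phantom"])
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "fraction_recovery.csv", index=False)

    print(df.round(4).to_string(index=False))
    print(f"\nmean |error| = {res['mean_abs_error_pp']:.3f} pp, "
          f"max |error| = {res['max_abs_error_pp']:.3f} pp "
          f"over {args.n_phantoms} phantoms (cortex share 60-80%)")


if __name__ == "__main__":
    main()
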