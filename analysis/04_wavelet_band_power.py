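"""Quantify infradian rhythm strength by Morlet wavelet band power.

Computes each participant's mean 26-32-day wavelet power from nightly
temperature maxima and summarises it per category (mean +- SE).  Cyclic
females should carry far more band power than either acyclic group.
"""
import argparse
from pathlib import Path

import pandas as pd

from thermovar.spectral import cohort_band_power, group_band_summary


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    nightly = pd.read_csv(args.out / "nightly.csv", parse_dates=["date"])
    labels = pd.read_csv(args.out / "labels.csv")
    cat = labels.set_index("pid")["category"]

    bp = cohort_band_power(nightly)
    bp.to_csv(args.out / "bandpower.csv", index=False)
    summ = group_band_summary(bp, cat)
    summ.to_csv(args.out / "bandpower_summary.csv", index=False)

    print("26-32-day band power by category (mean +- SE):")
    for _, r in summ.iterrows():
        print(f"  {r['category']:>15}: {r['mean_power']:.4f} +- {r['se_power']:.4f} (n={r['n']})")
    s = summ.set_index("category")["mean_power"]
    print(f"cyclic/male power ratio: {s['cyclic_female']/s['male']:.1f}")
    print(f"tables -> {args.out/'bandpower.csv'}, {args.out/'bandpower_summary.csv'}")


if __name__ == "__main__":
    main()
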