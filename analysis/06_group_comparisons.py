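"""Statistical comparison of the three categories.

Runs the 9-comparison Mann-Whitney family (3 category pairs x 3 time
states) on every variability metric, Cohen's d effect sizes for mean and
variance, Kruskal-Wallis on final cumulative errors (threshold 0.0025),
and the below/above-50 age-bin contrasts of median nightly maxima.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from thermovar.compare import (
    N_COMPARISONS_STATES,
    age_bin_contrasts,
    comparisons_frame,
    effect_size_table,
    kruskal_cumerr,
    mwu_bonferroni,
)
from thermovar.pipeline import CATEGORY_PAIRS
from thermovar.variability import STATES


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    metrics = pd.read_csv(args.out / "metrics.csv")
    labels = pd.read_csv(args.out / "labels.csv")
    roster = pd.read_csv(args.out / "cohort.csv")
    nightly = pd.read_csv(args.out / "nightly.csv", parse_dates=["date"])
    cum = pd.read_csv(args.out / "cumulative_error.csv")
    cat = labels.set_index("pid")["category"]

    results, eff = [], []
    for metric in ("mean", "variance", "cv", "pv", "d"):
        for state in STATES:
            sub = metrics[metrics["state"] == state]
            groups = {c: sub.loc[sub["category"] == c, metric].to_numpy()
                      for c in cat.unique()}
            pairs = [p for p in CATEGORY_PAIRS if all(len(groups.get(g, ())) >= 2 for g in p)]
            if pairs:
                results += mwu_bonferroni(groups, pairs, N_COMPARISONS_STATES,
                                          metric=f"{metric}/{state}")
                if metric in ("mean", "variance"):
                    eff.append(effect_size_table(groups, pairs, metric=f"{metric}/{state}"))
    comparisons = comparisons_frame(results)
    comparisons.to_csv(args.out / "comparisons.csv", index=False)
    effects = pd.concat(eff, ignore_index=True)
    effects.to_csv(args.out / "effect_sizes.csv", index=False)

    finals = cum.sort_values("t").groupby("pid")["cum"].last()
    fin_groups = {c: finals[cat.loc[finals.index] == c].to_numpy() for c in cat.unique()}
    h, p, sig = kruskal_cumerr(fin_groups)

    med = nightly.groupby("pid")["temp_max"].median().rename("median_temp_max")
    fem = roster.set_index("pid").join(med).reset_index()
    fem = fem[fem["sex"] == "female"].dropna(subset=["median_temp_max"])
    age = age_bin_contrasts(fem)
    age.to_csv(args.out / "age_bin_contrasts.csv", index=False)

    n_sig = int(comparisons["significant"].sum())
    print(f"{len(comparisons)} pairwise tests, {n_sig} significant after "
          f"Bonferroni (family of {N_COMPARISONS_STATES})")
    print("sleep-mean effect sizes (Cohen's d):")
    print(effects[effects['metric'] == 'mean/sleep'].to_string(index=False))
    print(f"Kruskal-Wallis on final cumulative error: H={h:.3f}, p={p:.3f}, "
          f"significant at 0.0025: {sig}")
    print(f"{int(age['significant'].sum())}/{len(age)} age-bin contrasts significant")
    print(f"tables -> {args.out}/comparisons.csv, effect_sizes.csv, age_bin_contrasts.csv")


if __name__ == "__main__":
    main()
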