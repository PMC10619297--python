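"""Clean the raw streams and annotate sleep/wake.

Applies the cleaning cascade (dedupe -> MET < 0.5 artifact filter ->
0.05/0.95 per-participant quantile band), selects one summary row per night
(longest sleep), annotates each sample's state from the summaries, and
applies the 70% daily-completeness filter.  Writes annotated streams back to
scratch/, the selected nightly table and the drop audit to results/study/.
"""
import argparse
from pathlib import Path

import pandas as pd

from thermovar.preprocess import (
    annotate_sleep_wake,
    clean_series,
    completeness_filter,
    select_nightly_rows,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--raw-dir", type=Path, default=Path("scratch/study_raw"))
    ap.add_argument("--clean-dir", type=Path, default=Path("scratch/study_clean"))
    ap.add_argument("--out", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    nightly = select_nightly_rows(pd.read_parquet(args.raw_dir / "nightly_raw.parquet"))
    args.clean_dir.mkdir(parents=True, exist_ok=True)
    audits, frames = [], {}
    for f in sorted(args.raw_dir.glob("*.parquet")):
        if f.name == "nightly_raw.parquet":
            continue
        raw = pd.read_parquet(f)
        res = clean_series(raw)
        pid = raw["pid"].iloc[0]
        ann = annotate_sleep_wake(res.clean, nightly[nightly["pid"] == pid])
        frames[pid] = ann
        audits.append(res.audit)

    audit = pd.concat(audits, ignore_index=True)
    sample_minutes = 5
    retained = completeness_filter(frames, sample_minutes)
    for pid in retained:
        frames[pid].to_parquet(args.clean_dir / f"{pid}.parquet", index=False)
    nightly[nightly["pid"].isin(retained)].to_csv(args.out / "nightly.csv", index=False)
    audit.to_csv(args.out / "drop_audit.tsv", sep="\t", index=False)

    total = sum(len(f) for f in frames.values()) + len(audit)
    print(f"cleaned {len(frames)} participants: {len(audit)} samples dropped "
          f"({audit['reason'].value_counts().to_dict()}) of {total}")
    print(f"completeness filter retained {len(retained)}/{len(frames)} participants")
    print(f"nightly table -> {args.out/'nightly.csv'}; clean streams -> {args.clean_dir}/")


if __name__ == "__main__":
    main()
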