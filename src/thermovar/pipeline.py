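"""End-to-end orchestration: simulate -> preprocess -> classify -> spectral
-> metrics -> compare, as one reproducible run with a manifest.

Every stage is a plain function over DataFrames so the analysis scripts, the
tests and the acceptance script can call them directly; :func:`run_pipeline`
chains them and writes all numeric outputs as CSV (figures are optional and
never the only carrier of a number).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import (
    N_COMPARISONS_STATES,
    age_bin_contrasts,
    comparisons_frame,
    effect_size_table,
    kruskal_cumerr,
    mwu_bonferroni,
)
from .cyclicity import DEFAULT_MAX_LAG, DEFAULT_THETA, classify_cohort
from .errors import ConfigError
from .preprocess import annotate_sleep_wake, clean_series, completeness_filter, select_nightly_rows
from .spectral import DEFAULT_BAND, cohort_band_power, group_band_summary
from .synth import SimConfig, generate_cohort
from .variability import STATES, cumulative_error_table, metric_table, state_subset_and_smooth

CATEGORY_PAIRS = [
    ("cyclic_female", "acyclic_female"),
    ("cyclic_female", "male"),
    ("acyclic_female", "male"),
]


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    q_low: float = 0.05
    q_high: float = 0.95
    met_threshold: float = 0.5
    min_completeness: float = 0.70
    signal: str = "temp_trend_dev"
    k: int = 3
    linkage: str = "average"
    theta: float = DEFAULT_THETA
    max_lag: int | None = None  # None: 90-day grid capped to the cohort span
    band: tuple[float, float] = DEFAULT_BAND
    se_form: str = "printed"
    cumerr_nights: int = 60
    make_plots: bool = False
    write_minute: bool = False

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["sim"] = json.loads(self.sim.to_json())
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def derive_categories(labels: pd.DataFrame, roster: pd.DataFrame) -> pd.Series:
    """Study category per pid: males are one category regardless of the
    classifier output; females split into cyclic/acyclic by the classifier."""
    sex = roster.set_index("pid")["sex"]
    lab = labels.set_index("pid")["label"]
    out = {}
    for pid in lab.index:
        if sex.get(pid) == "male":
            out[pid] = "male"
        else:
            out[pid] = "cyclic_female" if lab[pid] == "cyclic" else "acyclic_female"
    return pd.Series(out, name="category")


def preprocess_cohort(
    frames: dict[str, pd.DataFrame],
    nightly_raw: pd.DataFrame,
    cfg: RunConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame, list[str]]:
    """Clean + annotate every participant; returns (annotated frames,
    selected nightly rows, audit log, retained pids)."""
    nightly = select_nightly_rows(nightly_raw)
    annotated: dict[str, pd.DataFrame] = {}
    audits = []
    for pid, raw in frames.items():
        res = clean_series(raw, cfg.q_low, cfg.q_high, cfg.met_threshold)
        nights = nightly[nightly["pid"] == pid]
        annotated[pid] = annotate_sleep_wake(res.clean, nights)
        audits.append(res.audit)
    audit = pd.concat(audits, ignore_index=True) if audits else pd.DataFrame()
    sample_minutes = cfg.sim.sample_minutes
    retained = completeness_filter(annotated, sample_minutes, cfg.min_completeness)
    annotated = {p: annotated[p] for p in retained}
    return annotated, nightly, audit, retained


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute the full synthetic study and write tables under ``outdir``.

    Returns a result dict with the main in-memory tables.  Deterministic for
    a fixed config (seed included); the manifest records the config hash and
    per-stage row counts.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.config_hash(), "seed": cfg.sim.seed,
                      "version": __version__, "stages": {}}

    # -- simulate --------------------------------------------------------
    roster, frames, nightly_raw = generate_cohort(cfg.sim)
    roster.to_csv(out / "cohort.csv", index=False)
    manifest["stages"]["simulate"] = {
        "participants": len(roster), "nightly_rows": len(nightly_raw),
        "minute_rows": int(sum(len(f) for f in frames.values()))}
    if cfg.write_minute:
        raw_dir = out / "raw"
        raw_dir.mkdir(exist_ok=True)
        for pid, df in frames.items():
            df.to_parquet(raw_dir / f"{pid}.parquet", index=False)

    # -- preprocess ------------------------------------------------------
    annotated, nightly, audit, retained = preprocess_cohort(frames, nightly_raw, cfg)
    nightly.to_csv(out / "nightly.csv", index=False)
    audit.to_csv(out / "drop_audit.tsv", sep="\t", index=False)
    manifest["stages"]["preprocess"] = {
        "retained_participants": len(retained), "dropped_samples": len(audit)}

    # -- classify --------------------------------------------------------
    labels, excluded = classify_cohort(
        nightly[nightly["pid"].isin(retained)], signal=cfg.signal,
        max_lag=cfg.max_lag, k=cfg.k, method=cfg.linkage, theta=cfg.theta)
    categories = derive_categories(labels, roster)
    labels = labels.merge(categories.rename("category"), left_on="pid", right_index=True)
    labels.to_csv(out / "labels.csv", index=False)
    manifest["stages"]["classify"] = {
        "labelled": len(labels), "excluded": len(excluded),
        "cyclic": int((labels["label"] == "cyclic").sum())}

    # -- spectral --------------------------------------------------------
    bp = cohort_band_power(nightly[nightly["pid"].isin(labels["pid"])],
                           lo=cfg.band[0], hi=cfg.band[1])
    bp.to_csv(out / "bandpower.csv", index=False)
    band_summary = group_band_summary(bp, categories)
    band_summary.to_csv(out / "bandpower_summary.csv", index=False)
    manifest["stages"]["spectral"] = {"participants": len(bp)}

    # -- metrics ---------------------------------------------------------
    metrics = metric_table(annotated)
    metrics = metrics.merge(categories.rename("category"), left_on="pid", right_index=True)
    metrics.to_csv(out / "metrics.csv", index=False)

    nightly_by_pid = {
        pid: grp.sort_values("date")["temp_max"].to_numpy()[: cfg.cumerr_nights]
        for pid, grp in nightly.groupby("pid") if pid in categories.index
    }
    cum_table, trajs = cumulative_error_table(nightly_by_pid, categories, form=cfg.se_form)
    cum_table.to_csv(out / "cumulative_error.csv", index=False)
    manifest["stages"]["metrics"] = {"metric_rows": len(metrics),
                                     "cumerr_participants": len(trajs)}

    # -- compare ---------------------------------------------------------
    results = []
    for metric_name in ("mean", "variance", "cv", "pv", "d"):
        for state in STATES:
            sub = metrics[metrics["state"] == state]
            groups = {c: sub.loc[sub["category"] == c, metric_name].to_numpy()
                      for c in categories.unique()}
            pairs = [p for p in CATEGORY_PAIRS if all(len(groups.get(g, ())) >= 2 for g in p)]
            if not pairs:
                continue
            res = mwu_bonferroni(groups, pairs, N_COMPARISONS_STATES,
                                 metric=f"{metric_name}/{state}")
            results.extend(res)
    comparisons = comparisons_frame(results)
    comparisons.to_csv(out / "comparisons.csv", index=False)

    eff_rows = []
    for metric_name in ("mean", "variance"):
        for state in ("wake", "sleep"):
            sub = metrics[metrics["state"] == state]
            groups = {c: sub.loc[sub["category"] == c, metric_name].to_numpy()
                      for c in categories.unique()}
            pairs = [p for p in CATEGORY_PAIRS if all(len(groups.get(g, ())) >= 2 for g in p)]
            if pairs:
                eff_rows.append(effect_size_table(groups, pairs, metric=f"{metric_name}/{state}"))
    effects = pd.concat(eff_rows, ignore_index=True) if eff_rows else pd.DataFrame()
    effects.to_csv(out / "effect_sizes.csv", index=False)

    finals = {c: np.array([t.final for p, t in trajs.items() if categories.get(p) == c])
              for c in categories.unique()}
    finals = {c: v for c, v in finals.items() if len(v) >= 2}
    if len(finals) >= 2:
        h, p, sig = kruskal_cumerr(finals)
    else:
        h, p, sig = np.nan, np.nan, False
    kw = pd.DataFrame([{"test": "kruskal_final_cumerr", "H": h, "p": p,
                        "significant_at_0.0025": sig}])
    kw.to_csv(out / "kruskal_cumerr.csv", index=False)

    med_max = nightly.groupby("pid")["temp_max"].median().rename("median_temp_max")
    per_part = roster.set_index("pid").join(med_max).reset_index()
    fem = per_part[per_part["sex"] == "female"].dropna(subset=["median_temp_max"])
    age_tbl = age_bin_contrasts(fem) if len(fem) else pd.DataFrame()
    age_tbl.to_csv(out / "age_bin_contrasts.csv", index=False)
    manifest["stages"]["compare"] = {"comparisons": len(comparisons),
                                     "age_contrasts": len(age_tbl)}

    if cfg.make_plots:
        _make_plots(out, annotated, band_summary, trajs, categories)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"roster": roster, "labels": labels, "categories": categories,
            "bandpower": bp, "band_summary": band_summary, "metrics": metrics,
            "comparisons": comparisons, "effects": effects,
            "kruskal": kw, "age_contrasts": age_tbl, "manifest": manifest,
            "trajectories": trajs, "nightly": nightly, "annotated": annotated}


def _make_plots(out: Path, annotated, band_summary, trajs, categories) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)

    # hourly mean +- sd band over the cohort (day/night structure)
    frames = []
    for pid, df in annotated.items():
        d = df[df["state"].isin(("wake", "sleep"))]
        frames.append(pd.DataFrame({
            "hour": pd.to_datetime(d["timestamp"]).dt.hour,
            "temperature": d["temperature"]}))
    alld = pd.concat(frames, ignore_index=True)
    prof = alld.groupby("hour")["temperature"].agg(["mean", "std"])
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(prof.index, prof["mean"])
    ax.fill_between(prof.index, prof["mean"] - prof["std"], prof["mean"] + prof["std"], alpha=0.3)
    ax.set_xlabel("hour of day")
    ax.set_ylabel("temperature (deg C)")
    fig.tight_layout()
    fig.savefig(figdir / "hourly_profile.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(band_summary["category"], band_summary["mean_power"],
           yerr=band_summary["se_power"])
    ax.set_ylabel("26-32 d band power")
    fig.tight_layout()
    fig.savefig(figdir / "band_power.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 3))
    colors = {"cyclic_female": "tab:blue", "acyclic_female": "tab:cyan", "male": "tab:red"}
    for pid, tr in trajs.items():
        ax.plot(tr.times, tr.cum, color=colors.get(categories.get(pid), "gray"),
                alpha=0.3, lw=0.7)
    ax.set_xlabel("night")
    ax.set_ylabel("cumulative error")
    fig.tight_layout()
    fig.savefig(figdir / "cumulative_error.png", dpi=100)
    plt.close(fig)
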