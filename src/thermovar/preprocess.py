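"""Cleaning of raw minute-level streams and nightly summaries.

Order of the cleaning pipeline: de-duplication -> MET artifact filter ->
per-participant quantile filter (band estimated on MET-cleaned data so that
charging spikes cannot distort it).  Every dropped sample carries exactly one
drop reason (``duplicate``, ``met_artifact`` or ``quantile``), recorded in an
audit table, and retained + dropped always equals the input count.

The quantile band is estimated once per participant; re-applying the pipeline
with the stored band is a no-op (estimate-once semantics).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    EmptySeriesError,
    SchemaError,
    ValidationError,
)

DROP_REASONS = ("duplicate", "met_artifact", "quantile")


def _audit(df: pd.DataFrame, reason: str) -> pd.DataFrame:
    out = df[["pid", "timestamp"]].copy() if "pid" in df.columns else df[["timestamp"]].copy()
    out["reason"] = reason
    return out


def _empty_audit() -> pd.DataFrame:
    return pd.DataFrame(columns=["pid", "timestamp", "reason"])


def index_and_dedupe(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sort by local timestamp and drop duplicated time points (first kept).

    Returns ``(kept, audit)``.  Raises :class:`EmptySeriesError` on empty
    input and :class:`SchemaError` if the timestamp column is missing.
    """
    if "timestamp" not in raw.columns:
        raise SchemaError("input lacks a 'timestamp' column")
    if len(raw) == 0:
        raise EmptySeriesError("cannot index an empty series")
    df = raw.sort_values("timestamp", kind="stable")
    dup = df["timestamp"].duplicated(keep="first")
    return df[~dup].reset_index(drop=True), _audit(df[dup], "duplicate")


def met_artifact_filter(
    s: pd.DataFrame, met_threshold: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop samples whose MET is strictly below ``met_threshold``.

    A MET exactly at the threshold is retained (the drop rule is
    "recordings lower than 0.5").
    """
    if "met" not in s.columns:
        raise SchemaError("input lacks a 'met' column")
    low = s["met"].to_numpy() < met_threshold
    return s[~low].reset_index(drop=True), _audit(s[low], "met_artifact")


def quantile_band(
    temperatures: np.ndarray, q_low: float, q_high: float
) -> tuple[float, float]:
    """Per-participant retention band by linear-interpolation quantiles."""
    if not (0 <= q_low < q_high <= 1):
        raise ConfigError(f"quantile band: need 0 <= q_low < q_high <= 1, got ({q_low}, {q_high})")
    t = np.asarray(temperatures, dtype=float)
    return float(np.quantile(t, q_low)), float(np.quantile(t, q_high))


def quantile_filter(
    s: pd.DataFrame,
    q_low: float = 0.05,
    q_high: float = 0.95,
    bounds: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, tuple[float, float]]:
    """Drop samples strictly outside the participant's quantile band.

    If ``bounds`` is given the band is not re-estimated (idempotent
    re-application); otherwise it is computed from this input.  Returns
    ``(kept, audit, bounds)``.
    """
    if "temperature" not in s.columns:
        raise SchemaError("input lacks a 'temperature' column")
    if bounds is None:
        bounds = quantile_band(s["temperature"].to_numpy(), q_low, q_high)
    lo, hi = bounds
    t = s["temperature"].to_numpy()
    out = (t < lo) | (t > hi)
    return s[~out].reset_index(drop=True), _audit(s[out], "quantile"), bounds


@dataclass
class CleanResult:
    clean: pd.DataFrame
    audit: pd.DataFrame
    quantile_bounds: tuple[float, float]


def clean_series(
    raw: pd.DataFrame,
    q_low: float = 0.05,
    q_high: float = 0.95,
    met_threshold: float = 0.5,
    quantile_bounds: tuple[float, float] | None = None,
) -> CleanResult:
    """Full cleaning pipeline: dedupe -> MET filter -> quantile filter."""
    deduped, a1 = index_and_dedupe(raw)
    met_ok, a2 = met_artifact_filter(deduped, met_threshold)
    kept, a3, bounds = quantile_filter(met_ok, q_low, q_high, bounds=quantile_bounds)
    audit = pd.concat([a1, a2, a3], ignore_index=True) if (len(a1) + len(a2) + len(a3)) else _empty_audit()
    return CleanResult(clean=kept, audit=audit, quantile_bounds=bounds)


def select_nightly_rows(summaries: pd.DataFrame) -> pd.DataFrame:
    """Keep one summary row per (pid, date): the longest sleep episode,
    ties broken by the earliest sleep start."""
    for col in ("pid", "date", "sleep_duration", "sleep_start"):
        if col not in summaries.columns:
            raise SchemaError(f"nightly summaries lack a '{col}' column")
    df = summaries.sort_values(
        ["pid", "date", "sleep_duration", "sleep_start"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    return df.drop_duplicates(["pid", "date"], keep="first").reset_index(drop=True)


def annotate_sleep_wake(s: pd.DataFrame, nights: pd.DataFrame) -> pd.DataFrame:
    """Label each sample ``sleep`` if it falls inside a half-open
    [sleep_start, sleep_end) window, ``wake`` if its calendar date (or the
    preceding one, whose night extends into it) has a summary, ``unknown``
    otherwise.  Raises :class:`ValidationError` on overlapping windows."""
    df = s.copy()
    if nights.empty:
        df["state"] = "unknown"
        return df
    nw = nights.sort_values("sleep_start")
    starts = nw["sleep_start"].to_numpy(dtype="datetime64[ns]").astype(np.int64)
    ends = nw["sleep_end"].to_numpy(dtype="datetime64[ns]").astype(np.int64)
    if np.any(ends[:-1] > starts[1:]):
        raise ValidationError("overlapping sleep windows in nightly summaries")
    t = df["timestamp"].to_numpy(dtype="datetime64[ns]").astype(np.int64)
    idx = np.searchsorted(starts, t, side="right") - 1
    in_sleep = (idx >= 0) & (t < ends[np.clip(idx, 0, None)])
    # a night's record covers its own date and the following morning
    base_dates = pd.to_datetime(nights["date"]).dt.normalize()
    covered_dates = set(base_dates) | set(base_dates + pd.Timedelta(days=1))
    sample_dates = pd.to_datetime(df["timestamp"]).dt.normalize()
    has_summary = sample_dates.isin(covered_dates).to_numpy()
    state = np.where(in_sleep, "sleep", np.where(has_summary, "wake", "unknown"))
    df["state"] = state
    return df


def daily_completeness(s: pd.DataFrame, sample_minutes: int) -> pd.Series:
    """Observed / expected sample count for every calendar day in the
    participant's span (days with no data count as 0)."""
    expected = 1440 // sample_minutes
    dates = pd.to_datetime(s["timestamp"]).dt.normalize()
    counts = dates.value_counts().sort_index()
    full = pd.date_range(counts.index.min(), counts.index.max(), freq="D")
    return counts.reindex(full, fill_value=0) / expected


def completeness_filter(
    series_by_pid: dict[str, pd.DataFrame],
    sample_minutes: int,
    min_completeness: float = 0.70,
    required_months: list[str] | None = None,
) -> list[str]:
    """Return pids whose mean daily completeness is >= ``min_completeness``
    and (optionally) that have data in every required month (``YYYY-MM``)."""
    kept = []
    for pid, df in series_by_pid.items():
        if len(df) == 0:
            continue
        comp = daily_completeness(df, sample_minutes)
        if comp.mean() < min_completeness:
            continue
        if required_months:
            months = set(pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m"))
            if not set(required_months) <= months:
                continue
        kept.append(pid)
    return kept
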