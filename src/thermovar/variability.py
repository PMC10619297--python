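"""Temporal variability statistics of state-subset temperature series.

Per participant and time state (24 h, wake, sleep) the pipeline computes, on
an hourly-rolling-averaged series:

* mean and sample (n-1) variance;
* CV — coefficient of variation, sd / mean;
* PV — proportional variability, the mean of (1 - min/max) over all value
  pairs, in [0, 1] for positive data (computed in O(n log n) via sorted
  prefix sums; equal to the O(n^2) pairwise definition);
* D — consecutive disparity, the mean absolute log-ratio of consecutive
  values (order-sensitive, scale-invariant);
* cumulative error — the running sum of the standardised static error
  SE_i = ((t_i - m_p) / s_p) - 1 against a static population reference
  (m_p, s_p); an absolute-deviation variant |t_i - m_p|/s_p - 1 is available
  behind the ``form`` flag.

PV and D require strictly positive inputs, so they are computed on absolute
temperature (deg C), never on deviation signals.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    InsufficientDataError,
    NotApplicableError,
    UndefinedMetricError,
)

STATES = ("all24h", "wake", "sleep")
SE_FORMS = ("printed", "absolute")


# ---------------------------------------------------------------------------
# State subsetting and smoothing
# ---------------------------------------------------------------------------

def state_subset_and_smooth(
    s: pd.DataFrame,
    state: str,
    window_minutes: int = 60,
    min_frac: float = 0.5,
) -> pd.Series:
    """Subset an annotated series to one time state and apply a trailing
    hourly rolling mean within contiguous state bouts.

    ``state`` is one of ``all24h`` (wake + sleep), ``wake`` or ``sleep``.
    Smoothing never crosses a bout boundary (a state change or a time gap),
    and a window must contain at least ``min_frac`` of its nominal sample
    count to produce a value.  Returns a timestamp-indexed Series.
    """
    if state not in STATES:
        raise ConfigError(f"state: '{state}' not in {STATES}")
    if "state" not in s.columns:
        raise ConfigError("series is not annotated with a 'state' column")
    if state == "all24h":
        sub = s[s["state"].isin(("wake", "sleep"))]
    else:
        sub = s[s["state"] == state]
    if len(sub) == 0:
        raise InsufficientDataError(f"no samples in state '{state}'")
    ts = pd.to_datetime(sub["timestamp"])
    vals = pd.Series(sub["temperature"].to_numpy(dtype=float), index=ts)
    diffs = ts.diff().dt.total_seconds().to_numpy() / 60.0
    finite = diffs[np.isfinite(diffs)]
    interval = float(np.median(finite)) if len(finite) else float(window_minutes)
    gap = diffs > 1.5 * interval
    if state == "all24h":
        new_bout = gap
    else:
        new_bout = gap  # state already homogeneous; gaps include state changes
    bout = np.zeros(len(sub), dtype=np.int64)
    bout[1:] = np.cumsum(np.nan_to_num(new_bout[1:], nan=0.0).astype(bool))
    min_periods = max(1, int(np.ceil(min_frac * window_minutes / interval)))
    parts = []
    for _, grp in vals.groupby(bout):
        sm = grp.rolling(f"{window_minutes}min", min_periods=min_periods).mean()
        parts.append(sm)
    out = pd.concat(parts).dropna()
    if len(out) == 0:
        raise InsufficientDataError(f"smoothing left no samples in state '{state}'")
    return out


# ---------------------------------------------------------------------------
# Scalar variability metrics
# ---------------------------------------------------------------------------

def _values(x) -> np.ndarray:
    v = np.asarray(x.values if isinstance(x, pd.Series) else x, dtype=float)
    return v


def mean_variance(x) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) variance."""
    v = _values(x)
    if len(v) < 2:
        raise InsufficientDataError("mean/variance need >= 2 values")
    return float(v.mean()), float(v.var(ddof=1))


def cv(x) -> float:
    """Coefficient of variation: sample sd / mean."""
    v = _values(x)
    if len(v) < 2:
        raise InsufficientDataError("CV needs >= 2 values")
    m = v.mean()
    if m == 0:
        raise UndefinedMetricError("CV undefined for zero-mean series")
    return float(v.std(ddof=1) / m)


def pv(x) -> float:
    """Proportional variability: 2 * sum_{i<j} (1 - min/max) / (n(n-1)).

    Uses the sorted prefix-sum identity
    sum_{i<j} min/max = sum_j (sum_{i<j} z_i) / z_j on ascending values,
    which equals the O(n^2) pairwise definition for positive data.
    """
    v = _values(x)
    n = len(v)
    if n < 2:
        raise InsufficientDataError("PV needs >= 2 values")
    if np.any(v <= 0):
        raise UndefinedMetricError("PV requires strictly positive values")
    z = np.sort(v)
    prefix = np.concatenate(([0.0], np.cumsum(z)[:-1]))
    ratio_sum = float(np.sum(prefix / z))
    pairs = n * (n - 1) / 2.0
    return float(2.0 * (pairs - ratio_sum) / (n * (n - 1)))


def d_index(x) -> float:
    """Consecutive disparity: mean |ln(p_{i+1}/p_i)| over consecutive pairs."""
    v = _values(x)
    if len(v) < 2:
        raise InsufficientDataError("D needs >= 2 values")
    if np.any(v <= 0):
        raise UndefinedMetricError("D requires strictly positive values")
    return float(np.mean(np.abs(np.diff(np.log(v)))))


def metric_row(x, pid: str = "", state: str = "") -> dict:
    m, var = mean_variance(x)
    return {"pid": pid, "state": state, "mean": m, "variance": var,
            "cv": cv(x), "pv": pv(x), "d": d_index(x)}


def metric_table(annotated_by_pid: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """MetricRow table over all participants and the three time states."""
    rows = []
    for pid, df in annotated_by_pid.items():
        for state in STATES:
            try:
                ss = state_subset_and_smooth(df, state)
            except InsufficientDataError:
                continue
            rows.append(metric_row(ss, pid=pid, state=state))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cumulative error
# ---------------------------------------------------------------------------

@dataclass
class CumulativeErrorSeries:
    pid: str
    times: np.ndarray
    se: np.ndarray
    cum: np.ndarray
    m_p: float
    s_p: float
    form: str
    aligned: bool = False

    @property
    def final(self) -> float:
        return float(self.cum[-1])


def cumulative_error(
    values,
    m_p: float,
    s_p: float,
    form: str = "printed",
    pid: str = "",
    aligned: bool = False,
    times=None,
) -> CumulativeErrorSeries:
    """Static-error trajectory against a fixed population reference.

    printed  form: SE_i = ((t_i - m_p) / s_p) - 1
    absolute form: SE_i = |t_i - m_p| / s_p - 1
    ``cum`` is the prefix sum of SE.
    """
    if s_p <= 0:
        raise ConfigError(f"s_p: must be > 0, got {s_p}")
    if form not in SE_FORMS:
        raise ConfigError(f"form: '{form}' not in {SE_FORMS}")
    v = _values(values)
    if len(v) == 0:
        raise InsufficientDataError("cumulative error needs at least one value")
    dev = (v - m_p) if form == "printed" else np.abs(v - m_p)
    se = dev / s_p - 1.0
    if times is None:
        times = np.arange(len(v))
    return CumulativeErrorSeries(pid=pid, times=np.asarray(times), se=se,
                                 cum=np.cumsum(se), m_p=m_p, s_p=s_p,
                                 form=form, aligned=aligned)


def population_reference(values_by_pid: dict[str, np.ndarray]) -> tuple[float, float]:
    """Static reference for a comparison population: the mean of
    per-participant means and the mean of per-participant sds."""
    means, sds = [], []
    for v in values_by_pid.values():
        v = _values(v)
        if len(v) < 2:
            continue
        means.append(v.mean())
        sds.append(v.std(ddof=1))
    if not means:
        raise InsufficientDataError("no participant with >= 2 values")
    return float(np.mean(means)), float(np.mean(sds))


def cumulative_error_table(
    values_by_pid: dict[str, np.ndarray],
    groups: pd.Series | dict,
    form: str = "printed",
) -> tuple[pd.DataFrame, dict[str, CumulativeErrorSeries]]:
    """Per-participant cumulative-error trajectories against each
    participant's own population (category) reference.

    Returns a long-format table (pid, t, se, cum) and the trajectory objects.
    """
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    refs: dict[str, tuple[float, float]] = {}
    for cat in groups.unique():
        members = {p: v for p, v in values_by_pid.items() if groups.get(p) == cat}
        refs[cat] = population_reference(members)
    trajs: dict[str, CumulativeErrorSeries] = {}
    rows = []
    for pid, v in values_by_pid.items():
        cat = groups.get(pid)
        if cat is None or cat not in refs:
            continue
        m_p, s_p = refs[cat]
        tr = cumulative_error(v, m_p, s_p, form=form, pid=pid)
        trajs[pid] = tr
        rows.append(pd.DataFrame({"pid": pid, "t": tr.times, "se": tr.se, "cum": tr.cum}))
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    return table, trajs


# ---------------------------------------------------------------------------
# Cycle-phase alignment
# ---------------------------------------------------------------------------

def _sin_template(nbins: int = 64) -> np.ndarray:
    return np.sin(2.0 * np.pi * np.arange(nbins) / nbins)


def _template_value(template: np.ndarray, phase_frac: np.ndarray) -> np.ndarray:
    """Linear interpolation of a cyclic template at phase fractions in [0,1)."""
    nb = len(template)
    x = (phase_frac % 1.0) * nb
    i0 = np.floor(x).astype(int) % nb
    i1 = (i0 + 1) % nb
    w = x - np.floor(x)
    return (1 - w) * template[i0] + w * template[i1]


def estimate_cycle_day0(
    values,
    period: float,
    template: np.ndarray | None = None,
    step: float = 0.25,
) -> float:
    """Day index (mod period) of cycle day 0 — the temperature nadir
    preceding the rise — estimated by circular cross-correlation of the
    mean-centred series with a one-period template."""
    if period is None or not np.isfinite(period) or period <= 0:
        raise NotApplicableError("phase estimation requires a cyclic participant with a period")
    v = _values(values)
    if len(v) < period:
        raise InsufficientDataError("series shorter than one cycle")
    v = v - v.mean()
    if template is None:
        template = _sin_template()
    t = np.arange(len(v))
    offsets = np.arange(0.0, period, step)
    best_off, best_corr = 0.0, -np.inf
    tnorm = template - template.mean()
    for off in offsets:
        pred = _template_value(tnorm, (t - off) / period)
        denom = np.linalg.norm(pred) * np.linalg.norm(v)
        corr = float(pred @ v / denom) if denom > 0 else 0.0
        if corr > best_corr:
            best_corr, best_off = corr, off
    nadir_frac = float(np.argmin(template)) / len(template)
    return float((best_off + nadir_frac * period) % period)


def build_cycle_template(
    values_by_pid: dict[str, np.ndarray],
    periods: dict[str, float],
    nbins: int = 64,
) -> np.ndarray:
    """Mean one-cycle waveform of the cyclic group after period
    normalisation (first-pass alignment against a sinusoid)."""
    acc = np.zeros(nbins)
    wsum = np.zeros(nbins)
    for pid, v in values_by_pid.items():
        P = periods.get(pid)
        if P is None or not np.isfinite(P):
            continue
        v = _values(v)
        day0 = estimate_cycle_day0(v, P)
        frac = ((np.arange(len(v)) - day0) / P) % 1.0
        b = np.minimum((frac * nbins).astype(int), nbins - 1)
        vc = v - v.mean()
        np.add.at(acc, b, vc)
        np.add.at(wsum, b, 1.0)
    if np.any(wsum == 0):
        raise InsufficientDataError("cycle template has empty phase bins")
    tem = acc / wsum
    # rotate so the template starts at its nadir (cycle day 0 by convention)
    return np.roll(tem, -int(np.argmin(tem)))


def phase_align(
    values,
    period: float,
    template: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Circularly shift a nightly series so index 0 is cycle day 0.

    Returns ``(aligned, shift_days)`` with ``aligned = roll(values, -shift)``.
    Raises :class:`NotApplicableError` for acyclic participants (no period).
    """
    day0 = estimate_cycle_day0(values, period, template=template)
    shift = int(round(day0)) % max(1, int(round(period)))
    v = _values(values)
    return np.roll(v, -shift), float(shift)
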