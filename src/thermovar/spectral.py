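"""Infradian rhythm power via the continuous Morlet wavelet transform.

Nightly temperature-maximum series (one sample per day) are mean-centred and
transformed on a log-spaced scale grid covering periods of 2-64 days; rhythm
strength is the mean squared-modulus power over the 26-32-day period band,
excluding a cone-of-influence margin of one period length at each series edge.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .errors import ConfigError, InsufficientDataError

DEFAULT_BAND = (26.0, 32.0)    # days
PERIOD_RANGE = (2.0, 64.0)     # days spanned by the scale grid
N_SCALES = 64
MIN_NIGHTS = 64


@dataclass
class WaveletSpectrum:
    pid: str
    periods: np.ndarray     # days, ascending
    times: np.ndarray       # day index
    power: np.ndarray       # (period, time), squared modulus


def _fill_gaps(values: pd.Series) -> np.ndarray:
    s = values.sort_index()
    full = pd.date_range(s.index.min(), s.index.max(), freq="D")
    s = s.reindex(full).interpolate(method="linear", limit_direction="both")
    return s.to_numpy(dtype=float)


def cwt_morlet(
    nightly_values,
    periods: np.ndarray | None = None,
    pid: str = "",
) -> WaveletSpectrum:
    """Morlet CWT power spectrum of a daily series.

    ``nightly_values`` may be a plain array (already on a daily grid) or a
    date-indexed Series whose gaps are linearly interpolated.  The series is
    mean-centred (not variance-normalised) so between-participant amplitude
    differences remain visible.  Scale -> period conversion uses the Morlet
    central frequency with a 1-day sampling period.
    """
    if isinstance(nightly_values, pd.Series):
        x = _fill_gaps(nightly_values)
    else:
        x = np.asarray(nightly_values, dtype=float)
    if len(x) < MIN_NIGHTS:
        raise InsufficientDataError(f"need >= {MIN_NIGHTS} nightly values, have {len(x)}")
    x = x - x.mean()
    if periods is None:
        periods = np.logspace(np.log2(PERIOD_RANGE[0]), np.log2(PERIOD_RANGE[1]),
                              N_SCALES, base=2.0)
    fc = pywt.central_frequency("morl")
    scales = fc * np.asarray(periods, dtype=float)   # period = scale / fc at dt = 1 day
    coef, freqs = pywt.cwt(x, scales, "morl", sampling_period=1.0)
    power = np.abs(coef) ** 2
    out_periods = 1.0 / freqs
    return WaveletSpectrum(pid=pid, periods=out_periods, times=np.arange(len(x)),
                           power=power)


def band_power(
    spec: WaveletSpectrum,
    lo: float = DEFAULT_BAND[0],
    hi: float = DEFAULT_BAND[1],
) -> float:
    """Mean power over all (period, time) cells with lo <= period <= hi,
    excluding times within one period length of either series edge."""
    if not lo < hi:
        raise ConfigError(f"band: need lo < hi, got ({lo}, {hi})")
    rows = np.where((spec.periods >= lo) & (spec.periods <= hi))[0]
    if len(rows) == 0:
        raise ConfigError(f"band ({lo}, {hi}) outside the period grid")
    T = len(spec.times)
    cells = []
    for r in rows:
        p = spec.periods[r]
        valid = (spec.times >= p) & (spec.times <= T - 1 - p)
        if valid.any():
            cells.append(spec.power[r, valid])
    if not cells:
        raise InsufficientDataError("series too short: the whole band lies in the cone of influence")
    return float(np.mean(np.concatenate(cells)))


def cohort_band_power(
    nightly: pd.DataFrame,
    signal: str = "temp_max",
    lo: float = DEFAULT_BAND[0],
    hi: float = DEFAULT_BAND[1],
) -> pd.DataFrame:
    """Per-participant 26-32-day band power from a nightly-summary table."""
    rows = []
    for pid, grp in nightly.groupby("pid", sort=True):
        series = pd.Series(grp[signal].to_numpy(dtype=float),
                           index=pd.to_datetime(grp["date"]).dt.normalize())
        try:
            spec = cwt_morlet(series, pid=str(pid))
            bp = band_power(spec, lo, hi)
        except InsufficientDataError:
            continue
        rows.append({"pid": pid, "band_lo": lo, "band_hi": hi, "mean_power": bp})
    return pd.DataFrame(rows)


def group_band_summary(band_powers: pd.DataFrame, labels: pd.Series | dict) -> pd.DataFrame:
    """Per-category mean and standard error (sd/sqrt(n)) of band power."""
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    df = band_powers.copy()
    df["category"] = df["pid"].map(labels)
    out = []
    for cat, grp in df.groupby("category", sort=True):
        n = len(grp)
        if n < 2:
            raise InsufficientDataError(f"category '{cat}' has {n} member(s); SE undefined")
        vals = grp["mean_power"].to_numpy(dtype=float)
        out.append({"category": cat, "n": n, "mean_power": float(vals.mean()),
                    "se_power": float(vals.std(ddof=1) / np.sqrt(n))})
    return pd.DataFrame(out)
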