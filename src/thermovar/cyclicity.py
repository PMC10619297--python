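"""Cyclic/acyclic classification from nightly temperature summaries.

A participant's nightly signal (temperature trend deviation by default, or
nightly maximum) is summarised by its autocorrelation profile over lags of
0-90 days; cyclic participants show a wave-like profile with a peak in the
20-32-day lag window.  Profiles are compared pairwise by exact dynamic time
warping and grouped by agglomerative clustering; each cluster is labelled
cyclic or acyclic from its mean profile, with a per-individual override that
relabels members of a cyclic cluster lacking their own infradian ACF peak
(automating the manual reassignment step of the original workflow).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import find_peaks
from scipy.spatial.distance import squareform
from statsmodels.tsa.stattools import acf as sm_acf

from .errors import ConfigError, InsufficientDataError, ValidationError

PERIOD_WINDOW = (20.0, 32.0)   # days: candidate infradian periods
DEFAULT_MAX_LAG = 90           # days (~3 cycles within 6 months)
DEFAULT_THETA = 0.15           # ACF peak-prominence threshold
MAX_MISSING_RUN = 14           # nights; longer gaps disqualify
LINKAGE_METHODS = ("single", "complete", "average", "weighted", "ward")


@dataclass
class AutocorrProfile:
    pid: str
    lags: np.ndarray
    acf: np.ndarray
    source_signal: str


@dataclass
class CyclicityResult:
    pid: str
    cluster_id: int
    label: str                      # "cyclic" | "acyclic"
    override_applied: bool
    peak_period_days: float | None
    peak_acf: float | None


def _prepare_nightly(values: pd.Series) -> np.ndarray:
    """Reindex to a full daily grid, check gap rules, interpolate linearly."""
    s = values.sort_index()
    full = pd.date_range(s.index.min(), s.index.max(), freq="D")
    s = s.reindex(full)
    n = len(s)
    if s.notna().sum() < 60:
        raise InsufficientDataError(f"need >= 60 nightly values, have {int(s.notna().sum())}")
    gap_frac = s.isna().mean()
    if gap_frac > 0.20:
        raise InsufficientDataError(f"gap fraction {gap_frac:.2f} exceeds 0.20")
    # longest run of missing nights
    isna = s.isna().to_numpy()
    run = best = 0
    for v in isna:
        run = run + 1 if v else 0
        best = max(best, run)
    if best > MAX_MISSING_RUN:
        raise InsufficientDataError(f"missing run of {best} nights exceeds {MAX_MISSING_RUN}")
    s = s.interpolate(method="linear", limit_direction="both")
    return s.to_numpy(dtype=float), n


def compute_acf(
    nightly: pd.DataFrame,
    signal: str = "temp_trend_dev",
    max_lag: int = DEFAULT_MAX_LAG,
) -> AutocorrProfile:
    """Biased autocorrelation estimate of one participant's nightly signal
    at lags 0..max_lag (missing nights linearly interpolated)."""
    if signal not in nightly.columns:
        raise ConfigError(f"signal: '{signal}' not among nightly columns")
    pid = str(nightly["pid"].iloc[0]) if "pid" in nightly.columns and len(nightly) else ""
    series = pd.Series(
        nightly[signal].to_numpy(dtype=float),
        index=pd.to_datetime(nightly["date"]).dt.normalize(),
    )
    x, n = _prepare_nightly(series)
    if n <= max_lag:
        raise InsufficientDataError(f"series of {n} nights too short for max_lag={max_lag}")
    r = sm_acf(x, nlags=max_lag, fft=True, adjusted=False)
    return AutocorrProfile(pid=pid, lags=np.arange(max_lag + 1), acf=r, source_signal=signal)


@njit(cache=True)
def _dtw_dp(x, y):  # pragma: no cover - exercised through dtw_distance
    n, m = len(x), len(y)
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c = abs(x[i - 1] - y[j - 1])
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = c + best
    return D[n, m]


def dtw_distance(a, b) -> float:
    """Exact full-window DTW with absolute-difference local cost.

    Accepts :class:`AutocorrProfile` objects (which must share a lag grid)
    or plain 1-D arrays.  Symmetric; zero iff the sequences are identical.
    """
    if isinstance(a, AutocorrProfile) and isinstance(b, AutocorrProfile):
        if len(a.lags) != len(b.lags) or not np.array_equal(a.lags, b.lags):
            raise ValidationError("mismatched lag grids")
        x, y = a.acf, b.acf
    else:
        x, y = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("cannot warp an empty sequence")
    return float(_dtw_dp(np.ascontiguousarray(x, dtype=np.float64),
                         np.ascontiguousarray(y, dtype=np.float64)))


def pairwise_dtw(profiles: list[AutocorrProfile]) -> np.ndarray:
    n = len(profiles)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dtw_distance(profiles[i], profiles[j])
    return D


def _mds_embed(D: np.ndarray, ndim: int = 8) -> np.ndarray:
    """Deterministic classical-MDS embedding of a distance matrix (used for
    the ward linkage option, which requires Euclidean coordinates)."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    k = min(ndim, int(np.sum(w > 1e-12)))
    if k == 0:
        return np.zeros((n, 1))
    return v[:, :k] * np.sqrt(w[:k])


def cluster_profiles(dist: np.ndarray, k: int = 3, method: str = "average") -> np.ndarray:
    """Agglomerative clustering of a precomputed distance matrix, cut at k."""
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-10):
        raise ValidationError("distance matrix must have a zero diagonal")
    if k > n or k < 1:
        raise ConfigError(f"k: need 1 <= k <= n={n}, got {k}")
    if method not in LINKAGE_METHODS:
        raise ConfigError(f"linkage: '{method}' not in {LINKAGE_METHODS}")
    if n == 1:
        return np.array([1])
    if method == "ward":
        Z = linkage(_mds_embed(dist), method="ward")
    else:
        Z = linkage(squareform(dist, checks=False), method=method)
    return fcluster(Z, t=k, criterion="maxclust")


def acf_peak(
    profile: AutocorrProfile | np.ndarray,
    window: tuple[float, float] = PERIOD_WINDOW,
    theta: float = DEFAULT_THETA,
) -> tuple[float, float] | None:
    """Highest wave-like ACF peak in the candidate period window, or None.

    A peak qualifies if it is a local maximum with prominence >= theta and
    height >= theta, and the profile shows the antiphase trough of a genuine
    oscillation: the ACF around half the peak lag dips below zero.  The
    trough requirement separates infradian waves from chance noise peaks.
    """
    r = profile.acf if isinstance(profile, AutocorrProfile) else np.asarray(profile, dtype=float)
    lags = profile.lags if isinstance(profile, AutocorrProfile) else np.arange(len(r))
    idx, _ = find_peaks(r, prominence=theta)
    lo, hi = window
    candidates = []
    for i in idx:
        if not (lo <= lags[i] <= hi) or r[i] < theta:
            continue
        half = int(round(lags[i] / 2))
        j = np.where(np.abs(lags - half) <= 1)[0]
        if len(j) and np.min(r[j]) < 0:
            candidates.append(i)
    if not candidates:
        return None
    best = max(candidates, key=lambda i: r[i])
    return float(lags[best]), float(r[best])


def assign_labels(
    cluster_ids: np.ndarray,
    profiles: list[AutocorrProfile],
    window: tuple[float, float] = PERIOD_WINDOW,
    theta: float = DEFAULT_THETA,
) -> list[CyclicityResult]:
    """Label clusters cyclic/acyclic from their mean profile; relabel members
    of cyclic clusters that lack an individual peak (override)."""
    cluster_ids = np.asarray(cluster_ids)
    results: list[CyclicityResult] = []
    cluster_label: dict[int, str] = {}
    for cid in np.unique(cluster_ids):
        members = [p.acf for p, c in zip(profiles, cluster_ids) if c == cid]
        mean_profile = np.mean(members, axis=0)
        has_peak = acf_peak(mean_profile, window, theta) is not None
        cluster_label[int(cid)] = "cyclic" if has_peak else "acyclic"
    for p, cid in zip(profiles, cluster_ids):
        peak = acf_peak(p, window, theta)
        label = cluster_label[int(cid)]
        override = False
        if label == "cyclic" and peak is None:
            label, override = "acyclic", True
        results.append(CyclicityResult(
            pid=p.pid, cluster_id=int(cid), label=label, override_applied=override,
            peak_period_days=peak[0] if (peak and label == "cyclic") else None,
            peak_acf=peak[1] if (peak and label == "cyclic") else None,
        ))
    return results


def classify_cohort(
    nightly: pd.DataFrame,
    signal: str = "temp_trend_dev",
    max_lag: int | None = None,
    k: int = 3,
    method: str = "average",
    theta: float = DEFAULT_THETA,
    window: tuple[float, float] = PERIOD_WINDOW,
) -> tuple[pd.DataFrame, list[str]]:
    """End-to-end classification of a nightly-summary table.

    ``max_lag=None`` picks the default 90-day grid, capped to the cohort's
    shortest daily span but never below twice the longest candidate period
    (all profiles must share one lag grid for DTW).  Returns a labels
    DataFrame (pid, cluster_id, label, override_applied, peak_period_days,
    peak_acf) and the list of pids excluded by the data sufficiency rules.
    """
    if max_lag is None:
        dates = pd.to_datetime(nightly["date"])
        spans = dates.groupby(nightly["pid"]).agg(lambda d: (d.max() - d.min()).days + 1)
        max_lag = int(min(DEFAULT_MAX_LAG, max(2 * int(PERIOD_WINDOW[1]), spans.min() - 1)))
    profiles: list[AutocorrProfile] = []
    excluded: list[str] = []
    for pid, grp in nightly.groupby("pid", sort=True):
        try:
            profiles.append(compute_acf(grp, signal=signal, max_lag=max_lag))
        except InsufficientDataError:
            excluded.append(str(pid))
    if len(profiles) < max(2, k):
        raise InsufficientDataError("not enough qualifying participants to cluster")
    D = pairwise_dtw(profiles)
    ids = cluster_profiles(D, k=k, method=method)
    results = assign_labels(ids, profiles, window=window, theta=theta)
    df = pd.DataFrame([r.__dict__ for r in results])
    return df, excluded
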