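"""Group-comparison layer: Mann-Whitney U families with Bonferroni
correction, Kruskal-Wallis on final cumulative errors, Cohen's d effect
sizes, and age-bin contrasts of median nightly maximum temperature."""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InsufficientDataError, UndefinedMetricError

#: Family sizes used by the study design: 3 category pairs x 3 time states,
#: and all 15 pairs of six age bins.
N_COMPARISONS_STATES = 9
N_COMPARISONS_AGE = 15
KRUSKAL_ALPHA = 0.01 / 4  # 0.0025: threshold Bonferroni-corrected for 4 comparisons


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    metric: str
    u_stat: float
    p_raw: float
    p_bonferroni: float
    n_comparisons: int
    significant: bool


def mwu(
    a,
    b,
    alternative: str = "two-sided",
    u_orientation: str = "min",
) -> tuple[float, float]:
    """Mann-Whitney-Wilcoxon U test.

    Exact null distribution when min(n_a, n_b) <= 8 and there are no ties,
    normal approximation with tie correction otherwise.  The reported U is
    min(U_a, U_b) by default (``u_orientation='first'`` reports U_a).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    u_a = float(res.statistic)
    u_b = len(a) * len(b) - u_a
    u = min(u_a, u_b) if u_orientation == "min" else u_a
    return u, float(res.pvalue)


def bonferroni(p: float, n_comparisons: int) -> float:
    return min(1.0, p * n_comparisons)


def mwu_bonferroni(
    values_by_group: dict[str, np.ndarray],
    pairs: list[tuple[str, str]],
    n_comparisons: int,
    metric: str = "",
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> list[ComparisonResult]:
    """Pairwise U tests with Bonferroni correction over a stated family size."""
    out = []
    for ga, gb in pairs:
        u, p = mwu(values_by_group[ga], values_by_group[gb], alternative=alternative)
        pb = bonferroni(p, n_comparisons)
        out.append(ComparisonResult(
            group_a=ga, group_b=gb, metric=metric, u_stat=u, p_raw=p,
            p_bonferroni=pb, n_comparisons=n_comparisons,
            significant=pb <= alpha,
        ))
    return out


def comparisons_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def kruskal_cumerr(
    final_cum_by_group: dict[str, np.ndarray],
    alpha: float = KRUSKAL_ALPHA,
) -> tuple[float, float, bool]:
    """Kruskal-Wallis H over final cumulative errors; significance at the
    0.01/4 = 0.0025 Bonferroni-corrected threshold."""
    groups = [np.asarray(v, dtype=float) for v in final_cum_by_group.values()]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InsufficientDataError("Kruskal-Wallis needs >= 2 groups with >= 2 values each")
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]):
        warnings.warn("all values identical across groups; H undefined, reporting 0")
        return 0.0, 1.0, False
    h, p = stats.kruskal(*groups)
    return float(h), float(p), bool(p <= alpha)


def cohens_d(a, b) -> float:
    """Cohen's d with the pooled (n-1-weighted) standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise InsufficientDataError("Cohen's d needs >= 2 values per group")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise UndefinedMetricError("Cohen's d undefined: zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def effect_size_table(
    values_by_group: dict[str, np.ndarray],
    pairs: list[tuple[str, str]],
    metric: str = "",
) -> pd.DataFrame:
    rows = []
    for ga, gb in pairs:
        rows.append({"group_a": ga, "group_b": gb, "metric": metric,
                     "cohens_d": cohens_d(values_by_group[ga], values_by_group[gb])})
    return pd.DataFrame(rows)


def age_bin_contrasts(
    per_participant: pd.DataFrame,
    value_col: str = "median_temp_max",
    bin_col: str = "age_bin",
    n_comparisons: int = N_COMPARISONS_AGE,
    split_age: int = 50,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """U tests of a per-participant statistic (median nightly maximum by
    default) between every below-``split_age`` bin and every
    above-``split_age`` bin, Bonferroni-corrected for the full bin-pair
    family size."""
    if value_col not in per_participant.columns or bin_col not in per_participant.columns:
        raise ConfigError(f"need columns '{value_col}' and '{bin_col}'")
    bins = sorted(per_participant[bin_col].dropna().unique(),
                  key=lambda s: int(str(s).split("-")[0]))
    lower = [b for b in bins if int(str(b).split("-")[0]) < split_age]
    upper = [b for b in bins if int(str(b).split("-")[0]) >= split_age]
    values = {b: per_participant.loc[per_participant[bin_col] == b, value_col]
              .dropna().to_numpy() for b in bins}
    results = []
    for bl in lower:
        for bu in upper:
            if len(values[bl]) < 2 or len(values[bu]) < 2:
                warnings.warn(f"skipping bin pair ({bl}, {bu}): empty or singleton bin")
                continue
            u, p = mwu(values[bl], values[bu])
            pb = bonferroni(p, n_comparisons)
            results.append(ComparisonResult(
                group_a=str(bl), group_b=str(bu), metric=value_col, u_stat=u,
                p_raw=p, p_bonferroni=pb, n_comparisons=n_comparisons,
                significant=pb <= alpha,
            ))
    return comparisons_frame(results) if results else pd.DataFrame(
        columns=[f.name for f in ComparisonResult.__dataclass_fields__.values()]
    )
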