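"""Inter-patient and local correlation statistics.

Spearman rank correlations between observed T1(TE) and perfusion measures
(PBF, QDP) at three spatial levels — cohort (one value per patient),
registered voxels, and subdivided areas — plus Wilcoxon rank-sum
comparisons of T1 between perfusion-defect and normal voxels, the relative
defect shortening ΔT1, and the correlation of local correlation
coefficients with median T1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05                      # raw significance level, no correction


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    kind: str = ""                # IPBF | IQDP | regPBF | subPBF | subQDP | regcorr | subcorr
    te_us: float | None = None
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p_value) and self.p_value < ALPHA)


@dataclass
class DefectComparison:
    median_t1_normal_ms: float
    median_t1_defect_ms: float
    delta_t1_percent: float
    statistic: float
    p_value: float
    n_normal: int
    n_defect: int
    direction: str = "not_evaluable"   # defect_shorter | defect_longer | no_significant_difference
    te_us: float | None = None


def _finite_pairs(x, y) -> tuple[np.ndarray, np.ndarray, int]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep], int(keep.sum())


def _rank_corr(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)          # average ranks on ties
    ry = sps.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def spearman(x, y, kind: str = "", te_us: float | None = None,
             exact_max_n: int = 9) -> CorrelationResult:
    """Spearman's ρ with pairwise deletion of non-finite pairs.

    ρ is the Pearson correlation of average-ranked values.  The p-value
    uses the t approximation with n−2 degrees of freedom; for n ≤
    ``exact_max_n`` it is computed exactly by enumerating all permutations
    of one rank vector.  Constant inputs give a degenerate (flagged)
    result.
    """
    x, y, n = _finite_pairs(x, y)
    if n < 3:
        raise ValueError(f"need at least 3 valid pairs, got {n}")
    rho = _rank_corr(x, y)
    if not np.isfinite(rho):
        return CorrelationResult(rho=np.nan, p_value=np.nan, n=n, kind=kind,
                                 te_us=te_us, degenerate=True)
    if n <= exact_max_n:
        p = _spearman_exact_p(x, y, rho)
    elif abs(rho) >= 1.0 - 1e-14:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(np.clip(2.0 * sps.t.sf(np.abs(t), n - 2), 0.0, 1.0))
    return CorrelationResult(rho=rho, p_value=p, n=n, kind=kind, te_us=te_us)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p-value over all n! orderings of y."""
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]                           # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc**2).sum()) * np.sqrt((ryc**2).sum(axis=1))
    rhos = (ryc @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= np.abs(rho_obs) - 1e-12))


def wilcoxon_ranksum(a, b, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of ``a``, p).

    Exact enumeration of the rank-sum distribution over all group
    assignments when both groups have at most ``exact_max_n`` observations
    (ties included); otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if len(a) + len(b) < 3:
        raise ValueError("need at least 3 observations in total")
    n1, n2 = len(a), len(b)
    ranks = sps.rankdata(np.concatenate([a, b]))
    w = float(ranks[:n1].sum())
    if n1 <= exact_max_n and n2 <= exact_max_n:
        sums = np.array([ranks[list(idx)].sum()
                         for idx in itertools.combinations(range(n1 + n2), n1)])
        p = 2.0 * min(np.mean(sums <= w + 1e-12), np.mean(sums >= w - 1e-12))
        return w, float(min(p, 1.0))
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return w, float(res.pvalue)


def interpatient_correlations(cohort: pd.DataFrame, te_list_us,
                              ) -> dict[str, list[CorrelationResult | None]]:
    """ρ_IPBF and ρ_IQDP per echo time from a per-patient cohort table.

    Expects columns ``median_t1_te{i}_ms`` (1-based TE index),
    ``median_pbf`` and ``qdp_percent``.  Missing entries are dropped
    pairwise; a TE with fewer than 3 complete pairs yields ``None``.
    """
    out: dict[str, list[CorrelationResult | None]] = {"IPBF": [], "IQDP": []}
    for i, te in enumerate(te_list_us, start=1):
        t1 = cohort[f"median_t1_te{i}_ms"]
        for kind, col, dest in (("IPBF", "median_pbf", "IPBF"),
                                ("IQDP", "qdp_percent", "IQDP")):
            try:
                res = spearman(t1, cohort[col], kind=kind, te_us=float(te))
            except ValueError:
                res = None
                warnings.warn(f"{kind} at TE{i}: fewer than 3 complete pairs",
                              stacklevel=2)
            out[dest].append(res)
    return out


def local_correlation_registered(t1_ms: np.ndarray, t1_valid: np.ndarray,
                                 warped_pbf: np.ndarray, mask: np.ndarray,
                                 te_us: float | None = None) -> CorrelationResult:
    """Voxel-wise Spearman of T1 against registered PBF inside ``mask``."""
    sel = np.asarray(mask, dtype=bool) & np.asarray(t1_valid, dtype=bool)
    return spearman(np.where(sel, t1_ms, np.nan).ravel(),
                    np.where(sel, warped_pbf, np.nan).ravel(),
                    kind="regPBF", te_us=te_us)


def local_correlation_subdivided(t1_area_medians, perf_area_values,
                                 kind: str = "subPBF",
                                 te_us: float | None = None) -> CorrelationResult:
    """Spearman over corresponding subdivided areas (both lungs pooled).

    ``perf_area_values`` holds per-area PBF medians (kind ``subPBF``) or
    per-area defect fractions in [0, 1] (kind ``subQDP``).  Areas without a
    valid T1 median must arrive as NaN and are dropped pairwise; an all-
    constant perfusion vector (e.g. every area fully defect or fully
    normal) yields a degenerate, flagged result.
    """
    x, y, n = _finite_pairs(t1_area_medians, perf_area_values)
    if n < 3:
        raise ValueError(f"need at least 3 paired areas, got {n}")
    if np.unique(y).size < 2 or np.unique(x).size < 2:
        return CorrelationResult(rho=np.nan, p_value=np.nan, n=n, kind=kind,
                                 te_us=te_us, degenerate=True)
    return spearman(x, y, kind=kind, te_us=te_us)


def defect_normal_comparison(t1_ms: np.ndarray, t1_valid: np.ndarray,
                             defect_labels: np.ndarray,
                             te_us: float | None = None) -> DefectComparison:
    """Compare median T1 between normal (label 1) and defect (label 2)
    voxels; ΔT1 = 100·(median_normal − median_defect)/median_normal."""
    valid = np.asarray(t1_valid, dtype=bool) & np.isfinite(t1_ms)
    normal = t1_ms[valid & (defect_labels == 1)]
    defect = t1_ms[valid & (defect_labels == 2)]
    if len(normal) == 0 or len(defect) == 0:
        return DefectComparison(
            median_t1_normal_ms=np.nan, median_t1_defect_ms=np.nan,
            delta_t1_percent=np.nan, statistic=np.nan, p_value=np.nan,
            n_normal=len(normal), n_defect=len(defect),
            direction="not_evaluable", te_us=te_us,
        )
    med_n = float(np.median(normal))
    med_d = float(np.median(defect))
    delta = 100.0 * (med_n - med_d) / med_n if med_n > 0 else np.nan
    stat, p = wilcoxon_ranksum(defect, normal)
    if p >= ALPHA:
        direction = "no_significant_difference"
    elif med_d < med_n:
        direction = "defect_shorter"
    else:
        direction = "defect_longer"
    return DefectComparison(
        median_t1_normal_ms=med_n, median_t1_defect_ms=med_d,
        delta_t1_percent=delta, statistic=stat, p_value=p,
        n_normal=len(normal), n_defect=len(defect),
        direction=direction, te_us=te_us,
    )


def correlation_of_correlations(median_t1_te1, local_rhos,
                                kind: str = "regcorr") -> CorrelationResult:
    """Inter-patient Spearman of median T1(TE1) with per-patient local ρ."""
    return spearman(median_t1_te1, local_rhos, kind=kind)


def mean_sd_n(values) -> tuple[float, float, int]:
    """Cohort presentation of local ρ: mean ± SD with n (finite entries)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return np.nan, np.nan, 0
    return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0, len(v)
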