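"""DCE perfusion quantification.

Chain: relative-enhancement conversion -> automatic arterial-input-function
(AIF) detection -> truncated-SVD deconvolution of the indicator-dilution
convolution C = (Δt·AIF) * (PBF·R) -> per-voxel pulmonary blood flow
PBF = max_t R(t) -> t_max / two-threshold Otsu defect classification ->
perfusion defects in percent (QDP) -> slab projection to the 2D UTE
geometry.  PBV and MTT follow from the central-volume principle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz

from .grid import ImageGrid
from .phantom import DCESeries

DEFAULT_SVD_LAMBDA = 0.15
DEFAULT_OTSU_BINS = 256
DEFAULT_AIF_PERCENTILE = 99.0
DEFAULT_AIF_TOP_N = 20
DEFAULT_ENHANCEMENT_FLOOR = 0.2
# mL/100mL/min per 1/s (60 s/min x 100 mL/100 mL); calibration constants
# such as tissue density/hematocrit fold into this single factor
DEFAULT_PBF_SCALE = 6000.0


@dataclass
class ConcentrationSeries:
    """Relative-enhancement series C(t) = (S − S0)/S0 on the DCE grid."""

    data: np.ndarray                 # (T, *grid.shape)
    grid: ImageGrid
    dt_s: float
    valid: np.ndarray                # voxels with usable baseline
    n_baseline: int


@dataclass
class AIFCurve:
    values: np.ndarray               # per frame, relative-enhancement units
    dt_s: float
    n_voxels: int
    peak_frame: int
    n_candidates: int = 0
    n_clamped: int = 0

    def __post_init__(self):
        neg = self.values < 0
        self.n_clamped = int(neg.sum())
        self.values = np.clip(np.asarray(self.values, dtype=float), 0.0, None)
        self.peak_frame = int(np.argmax(self.values))


@dataclass
class ResidualMaps:
    data: np.ndarray                 # (T, *grid.shape), zero outside mask
    mask: np.ndarray
    grid: ImageGrid
    dt_s: float
    svd_lambda: float


@dataclass
class PBFMap:
    pbf: np.ndarray                  # 1/s raw; NaN outside mask
    mask: np.ndarray
    grid: ImageGrid
    n_clamped: int = 0

    def calibrated(self, scale: float = DEFAULT_PBF_SCALE) -> np.ndarray:
        """PBF in mL/100 mL/min via a single configurable scale factor."""
        return self.pbf * scale


@dataclass
class DefectClassification:
    labels: np.ndarray               # 0 outside, 1 normal, 2 defect
    theta_low: float
    theta_high: float
    t_max: int
    qdp_percent: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]


def to_concentration(series: DCESeries, n_baseline: int = 3,
                     s0_floor: float = 0.05) -> ConcentrationSeries:
    """Per-voxel relative enhancement against the pre-contrast baseline.

    ``S0`` is the mean of the first ``n_baseline`` frames; voxels whose S0
    falls below ``s0_floor`` (air) are flagged invalid and zeroed.
    """
    t = series.n_frames
    if not 1 <= n_baseline < t:
        raise ValueError(f"n_baseline must be in [1, {t - 1}], got {n_baseline}")
    s0 = series.data[:n_baseline].mean(axis=0)
    valid = s0 > s0_floor
    conc = np.zeros_like(series.data)
    conc[:, valid] = series.data[:, valid] / s0[valid] - 1.0
    return ConcentrationSeries(data=conc, grid=series.grid, dt_s=series.dt_s,
                               valid=valid, n_baseline=n_baseline)


def detect_aif(conc: ConcentrationSeries, body_mask: np.ndarray,
               percentile: float = DEFAULT_AIF_PERCENTILE,
               top_n: int = DEFAULT_AIF_TOP_N,
               floor: float = DEFAULT_ENHANCEMENT_FLOOR) -> AIFCurve:
    """Automatic AIF detection.

    Candidates are enhancing voxels (peak > ``floor``) inside ``body_mask``
    in the top ``percentile`` of peak enhancement whose time-to-peak is at
    most the median time-to-peak of all enhancing voxels; the AIF is the
    mean curve of the ``top_n`` candidates with the highest peaks.
    """
    sel = np.asarray(body_mask, dtype=bool) & conc.valid
    curves = conc.data[:, sel]                            # (T, n)
    if curves.shape[1] == 0:
        raise ValueError("AIF detection failed: no candidate voxel")
    peaks = curves.max(axis=0)
    enhancing = peaks > floor
    if not np.any(enhancing):
        raise ValueError("AIF detection failed: no voxel exceeds the enhancement floor")
    ttp = np.argmax(curves, axis=0)
    med_ttp = np.median(ttp[enhancing])
    thr = np.percentile(peaks[enhancing], percentile)
    cand = enhancing & (peaks >= thr) & (ttp <= med_ttp)
    if not np.any(cand):
        cand = enhancing & (ttp <= med_ttp)
    n_cand = int(cand.sum())
    if n_cand < top_n:
        warnings.warn(
            f"only {n_cand} AIF candidates for requested top {top_n}; using all",
            stacklevel=2,
        )
    order = np.argsort(peaks[cand])[::-1][:top_n]
    chosen = curves[:, cand][:, order]
    return AIFCurve(values=chosen.mean(axis=1), dt_s=conc.dt_s,
                    n_voxels=chosen.shape[1], peak_frame=0, n_candidates=n_cand)


def deconvolve(conc: ConcentrationSeries, aif: AIFCurve, segmentation: np.ndarray,
               svd_lambda: float = DEFAULT_SVD_LAMBDA) -> ResidualMaps:
    """Voxel-wise deconvolution by truncated-SVD pseudo-inverse.

    The lower-triangular Toeplitz matrix built from Δt·AIF is decomposed
    once; singular values below ``svd_lambda``·σ_max are zeroed.
    """
    if not 0.0 < svd_lambda < 1.0:
        raise ValueError("svd_lambda must be in (0, 1)")
    if np.all(aif.values == 0):
        raise ValueError("AIF is identically zero")
    t = conc.data.shape[0]
    if len(aif.values) != t:
        raise ValueError("AIF frame count must match the concentration series")
    mask = (np.asarray(segmentation) > 0) & conc.valid
    a = conc.dt_s * toeplitz(aif.values, np.zeros(t))
    u, s, vt = np.linalg.svd(a)
    s_inv = np.where(s > svd_lambda * s[0], 1.0 / np.where(s > 0, s, 1.0), 0.0)
    pinv = (vt.T * s_inv[None, :]) @ u.T
    r = np.zeros_like(conc.data)
    r[:, mask] = pinv @ conc.data[:, mask]
    return ResidualMaps(data=r, mask=mask, grid=conc.grid, dt_s=conc.dt_s,
                        svd_lambda=svd_lambda)


def compute_pbf(residuals: ResidualMaps) -> PBFMap:
    """PBF_v = max_t R_v(t); negative maxima clamp to 0 (counted)."""
    if not np.any(residuals.mask):
        raise ValueError("no voxels in the residual maps")
    peak = residuals.data.max(axis=0)
    n_clamped = int(np.sum(peak[residuals.mask] < 0))
    pbf = np.where(residuals.mask, np.clip(peak, 0.0, None), np.nan)
    return PBFMap(pbf=pbf, mask=residuals.mask, grid=residuals.grid,
                  n_clamped=n_clamped)


def find_tmax(residuals: ResidualMaps, segmentation: np.ndarray | None = None) -> int:
    """Frame of maximum lung-mean R(t); ties break to the earliest frame."""
    mask = residuals.mask if segmentation is None \
        else (np.asarray(segmentation) > 0) & residuals.mask
    if not np.any(mask):
        raise ValueError("empty segmentation")
    mean_r = residuals.data[:, mask].mean(axis=1)
    return int(np.argmax(mean_r))


def otsu_two_thresholds(values: np.ndarray, n_bins: int = DEFAULT_OTSU_BINS
                        ) -> tuple[float, float]:
    """Two-threshold (three-class) Otsu by exhaustive bin-pair search.

    Histograms ``values`` into ``n_bins`` over [min, max] and maximizes the
    between-class variance of the three induced classes; thresholds are
    returned as bin-edge values with θ_low < θ_high.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    n_distinct = np.unique(v).size
    if n_distinct < 2:
        raise ValueError("degenerate histogram: all values identical")
    if n_distinct == 2:
        # only one separation exists; the upper threshold is nominal
        warnings.warn("degenerate histogram: two distinct values, upper "
                      "threshold set to the sample maximum", stacklevel=2)
        lo, hi = np.unique(v)
        return float(0.5 * (lo + hi)), float(hi)
    hist, edges = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
    p = hist / hist.sum()
    mids = 0.5 * (edges[:-1] + edges[1:])
    w = np.cumsum(p)
    m = np.cumsum(p * mids)
    mu_total = m[-1]

    # class [0..i], (i..j], (j..end] for threshold bins i < j
    w0 = w[:, None]
    m0 = m[:, None]
    w1 = w[None, :] - w0
    m1 = m[None, :] - m0
    w2 = 1.0 - w[None, :]
    m2 = mu_total - m[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (
            np.where(w0 > 0, m0**2 / w0, 0.0)
            + np.where(w1 > 0, m1**2 / w1, 0.0)
            + np.where(w2 > 0, m2**2 / w2, 0.0)
        )
    i_idx, j_idx = np.triu_indices(n_bins, k=1)
    flat = sigma_b[i_idx, j_idx]
    # tolerance-aware maximum with lexicographic (i, j) tie-break, so the
    # selected pair does not depend on summation order in near-ties
    cand = np.flatnonzero(flat >= flat.max() * (1.0 - 1e-9))
    best = cand[np.lexsort((j_idx[cand], i_idx[cand]))[0]]
    i, j = int(i_idx[best]), int(j_idx[best])
    return float(edges[i + 1]), float(edges[j + 1])


def classify_defects(residuals: ResidualMaps, t_max: int,
                     thresholds: tuple[float, float],
                     segmentation: np.ndarray) -> DefectClassification:
    """Label lung voxels with R(t_max) below θ_low as perfusion defect;
    QDP = 100·|defect|/|lung| over the segmented voxels."""
    theta_low, theta_high = thresholds
    if theta_low >= theta_high:
        raise ValueError("thresholds must satisfy theta_low < theta_high")
    mask = (np.asarray(segmentation) > 0) & residuals.mask
    r_tmax = residuals.data[t_max]
    labels = np.zeros(residuals.grid.shape, dtype=np.uint8)
    labels[mask] = np.where(r_tmax[mask] < theta_low, 2, 1)
    n_lung = int(mask.sum())
    qdp = 100.0 * float((labels == 2).sum()) / n_lung if n_lung else 0.0
    return DefectClassification(labels=labels, theta_low=theta_low,
                                theta_high=theta_high, t_max=int(t_max),
                                qdp_percent=qdp, mask=mask)


def _slab_indices(grid: ImageGrid, slice_center_mm: float, n: int = 3) -> np.ndarray:
    nz = grid.shape[0]
    centers = grid.origin[0] + (np.arange(nz) + 0.5) * grid.spacing[0]
    if not centers.min() - 0.5 * grid.spacing[0] <= slice_center_mm <= centers.max() + 0.5 * grid.spacing[0]:
        raise ValueError(
            f"slice centre {slice_center_mm} mm outside volume [{centers.min()}, {centers.max()}]"
        )
    return np.sort(np.argsort(np.abs(centers - slice_center_mm), kind="stable")[:n])


def project_to_slab(map3d: np.ndarray, grid: ImageGrid, slice_center_mm: float,
                    is_label: bool = False, n_slices: int = 3,
                    tie_priority: tuple[int, ...] = (2, 1, 0)
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Average the ``n_slices`` DCE partitions nearest the UTE slice centre.

    Continuous maps are averaged (NaN-aware); label maps take a per-voxel
    majority vote with ties resolved by ``tie_priority`` order (defect label
    first).  Returns (2D map, selected slice indices).
    """
    if grid.ndim != 3 or grid.shape[0] < n_slices:
        raise ValueError(f"need a 3D map with at least {n_slices} slices")
    idx = _slab_indices(grid, slice_center_mm, n_slices)
    slab = np.asarray(map3d)[idx]
    if not is_label:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(slab, axis=0), idx
    labels = np.unique(slab)
    counts = np.stack([(slab == lab).sum(axis=0) for lab in labels])
    maxc = counts.max(axis=0)
    out = np.zeros(slab.shape[1:], dtype=slab.dtype)
    undecided = np.ones(slab.shape[1:], dtype=bool)
    prio = [lab for lab in tie_priority if lab in labels]
    prio += [lab for lab in labels if lab not in prio]
    for lab in prio:
        k = np.nonzero(labels == lab)[0][0]
        take = undecided & (counts[k] == maxc)
        out[take] = lab
        undecided &= ~take
    return out, idx


def compute_pbv_mtt(conc: ConcentrationSeries, aif: AIFCurve,
                    segmentation: np.ndarray, pbf_map: PBFMap
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Blood volume PBV = ΣC/ΣAIF and transit time MTT = PBV/PBF (s).

    MTT is NaN where PBF is zero or invalid.
    """
    aif_sum = float(aif.values.sum())
    if aif_sum <= 0:
        raise ValueError("AIF integral is zero")
    mask = (np.asarray(segmentation) > 0) & conc.valid
    pbv = np.full(conc.grid.shape, np.nan)
    pbv[mask] = conc.data[:, mask].sum(axis=0) / aif_sum
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt = np.where(pbf_map.pbf > 0, pbv / pbf_map.pbf, np.nan)
    return pbv, mtt
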