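"""Per-voxel inversion-recovery T1 fitting at each echo time.

The signal model is the three-parameter magnitude inversion recovery

    S(TI) = |A − B·exp(−TI/T1*)|

followed by the Look-Locker correction T1 = T1*·(B/A − 1) appropriate for
continuous low-flip-angle sampling.  The least-squares problem is solved by
variable projection: for a candidate T1* the model is linear in (A, B) once
the magnitude sign pattern is fixed, and with ascending TIs the sign flips
at most once (negative before the zero crossing).  A coarse log-spaced T1*
grid followed by golden-section refinement minimizes the projected residual
for all voxels simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import ImageGrid, require_same_grid
from .phantom import TISeries

T1_WINDOW_MS = (100.0, 3000.0)   # plausibility window; outside => clamp + flag

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class IRFitResult:
    """Single-voxel fit. ``valid`` gates all downstream medians/correlations."""

    a: float
    b: float
    t1_star_ms: float
    t1_ms: float
    rmse: float
    valid: bool


@dataclass
class T1Map:
    """Per-voxel T1 (ms) at one echo time, with validity mask."""

    t1_ms: np.ndarray
    valid: np.ndarray
    te_us: float
    grid: ImageGrid
    n_fitted: int = 0
    n_invalid: int = 0


def _projected_fit(signals: np.ndarray, tis: np.ndarray, t1_stars: np.ndarray,
                   flip_candidates: np.ndarray):
    """Best (rss, A, B) per voxel at fixed per-voxel T1*.

    ``flip_candidates``: (nvox, nf) indices f; samples before f are negated.
    """
    nvox, nti = signals.shape
    e = np.exp(-tis[None, :] / t1_stars[:, None])         # (nvox, nti)
    s_e = e.sum(axis=1)
    s_ee = (e * e).sum(axis=1)
    det = nti * s_ee - s_e * s_e
    det = np.where(np.abs(det) < 1e-300, np.nan, det)
    best = np.full(nvox, np.inf)
    best_a = np.zeros(nvox)
    best_b = np.zeros(nvox)
    idx = np.arange(nti)[None, :]
    for j in range(flip_candidates.shape[1]):
        f = flip_candidates[:, j][:, None]
        y = np.where(idx < f, -signals, signals)          # signed data
        s_y = y.sum(axis=1)
        s_ey = (e * y).sum(axis=1)
        # y ≈ A − B·e  (least squares in A, B)
        a = (s_ee * s_y - s_e * s_ey) / det
        b = (s_e * s_y - nti * s_ey) / det
        rss = (y * y).sum(axis=1) - a * s_y + b * s_ey
        rss = np.maximum(rss, 0.0)
        upd = rss < best
        best = np.where(upd, rss, best)
        best_a = np.where(upd, a, best_a)
        best_b = np.where(upd, b, best_b)
    return best, best_a, best_b


def _flip_candidates(signals: np.ndarray, window: int = 5) -> np.ndarray:
    """Magnitude sign-flip positions to try: around the per-voxel signal
    minimum (the zero crossing of an IR curve) plus the no-flip ends."""
    nvox, nti = signals.shape
    k = np.argmin(signals, axis=1)
    offs = np.arange(-window, window + 2)
    cand = np.clip(k[:, None] + offs[None, :], 0, nti)
    ends = np.broadcast_to(np.array([0, nti]), (nvox, 2))
    return np.concatenate([cand, ends], axis=1)


def fit_ir_curves(
    signals: np.ndarray,
    tis_ms: np.ndarray,
    coarse_points: int = 64,
    refine_iters: int = 40,
):
    """Vectorized magnitude-IR fit for ``signals`` of shape (nvox, nTI).

    Returns arrays (a, b, t1_star, t1, rmse, valid).
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    tis = np.asarray(tis_ms, dtype=float)
    if tis.ndim != 1 or tis.size < 3:
        raise ValueError("need at least 3 TI samples")
    if np.any(np.diff(tis) <= 0):
        raise ValueError("TIs must be strictly ascending")
    if signals.shape[1] != tis.size:
        raise ValueError("signal length must match the TI list")
    nvox = signals.shape[0]

    bad = ~np.all(np.isfinite(signals), axis=1)
    work = np.where(bad[:, None], 0.0, signals)
    flips = _flip_candidates(work)

    lo_ms, hi_ms = 0.5 * T1_WINDOW_MS[0], 1.5 * T1_WINDOW_MS[1]
    grid = np.geomspace(lo_ms, hi_ms, coarse_points)
    rss_grid = np.empty((coarse_points, nvox))
    for i, t1s in enumerate(grid):
        rss_grid[i], _, _ = _projected_fit(work, tis, np.full(nvox, t1s), flips)
    besti = np.argmin(rss_grid, axis=0)
    lo = grid[np.maximum(besti - 1, 0)]
    hi = grid[np.minimum(besti + 1, coarse_points - 1)]

    a_br, b_br = lo.copy(), hi.copy()
    for _ in range(refine_iters):
        c = b_br - _GOLDEN * (b_br - a_br)
        d = a_br + _GOLDEN * (b_br - a_br)
        fc, _, _ = _projected_fit(work, tis, c, flips)
        fd, _, _ = _projected_fit(work, tis, d, flips)
        left = fc < fd
        b_br = np.where(left, d, b_br)
        a_br = np.where(left, a_br, c)
    t1_star = 0.5 * (a_br + b_br)
    rss, a, b = _projected_fit(work, tis, t1_star, flips)
    rmse = np.sqrt(rss / tis.size)

    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = t1_star * (b / a - 1.0)
    valid = (
        ~bad
        & np.isfinite(a) & np.isfinite(b) & np.isfinite(t1)
        & (a > 0) & (b > a) & (t1_star > 0)
    )
    # degenerate flat/zero signals fit A=B=0 perfectly but carry no T1
    valid &= np.ptp(work, axis=1) > 0
    inside = (t1 >= T1_WINDOW_MS[0]) & (t1 <= T1_WINDOW_MS[1])
    t1 = np.clip(t1, T1_WINDOW_MS[0], T1_WINDOW_MS[1])
    valid &= inside
    t1 = np.where(np.isfinite(t1), t1, 0.0)
    return a, b, t1_star, t1, rmse, valid


def fit_ir_voxel(signal: np.ndarray, tis_ms: np.ndarray) -> IRFitResult:
    """Fit one voxel's TI time-course; NaNs yield an invalid result."""
    signal = np.asarray(signal, dtype=float).ravel()
    a, b, t1s, t1, rmse, valid = fit_ir_curves(signal[None, :], tis_ms)
    return IRFitResult(
        a=float(a[0]), b=float(b[0]), t1_star_ms=float(t1s[0]),
        t1_ms=float(t1[0]), rmse=float(rmse[0]), valid=bool(valid[0]),
    )


def map_t1(series: TISeries, segmentation: np.ndarray) -> T1Map:
    """Fit every segmented voxel of a TI series; background untouched."""
    segmentation = np.asarray(segmentation)
    if segmentation.shape != series.grid.shape:
        raise ValueError(
            f"grid mismatch: series {series.grid.shape} vs segmentation {segmentation.shape}"
        )
    mask = segmentation > 0
    t1_img = np.full(series.grid.shape, np.nan)
    valid_img = np.zeros(series.grid.shape, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        import warnings

        warnings.warn("empty segmentation: returning empty T1 map", stacklevel=2)
        return T1Map(t1_ms=t1_img, valid=valid_img, te_us=series.te_us,
                     grid=series.grid, n_fitted=0, n_invalid=0)
    signals = series.data[:, mask].T                      # (nvox, nTI)
    _, _, _, t1, _, valid = fit_ir_curves(signals, series.tis_ms)
    t1_img[mask] = np.where(valid, t1, np.nan)
    valid_img[mask] = valid
    return T1Map(t1_ms=t1_img, valid=valid_img, te_us=series.te_us,
                 grid=series.grid, n_fitted=n, n_invalid=int(n - valid.sum()))


def median_t1(t1map: T1Map, region: np.ndarray) -> tuple[float, int]:
    """Median over valid voxels of ``region``; returns (median_ms, count)."""
    region = np.asarray(region, dtype=bool)
    sel = region & t1map.valid
    n = int(sel.sum())
    if n == 0:
        raise ValueError("region does not intersect the validity mask")
    return float(np.median(t1map.t1_ms[sel])), n
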