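"""Synthetic digital lung phantom with known ground truth.

The phantom emulates, at desk scale, the two acquisitions the pipeline
analyses:

* an inversion-recovery multi-echo 2D UTE series for echo-time-dependent
  T1 mapping — each voxel holds a two-compartment mixture (blood and
  extravascular "tissue" protons) whose T2*-weighted contributions make the
  observed T1 depend on the echo time, and
* a 4D dynamic contrast-enhanced (DCE) series — tissue curves are formed by
  convolving a gamma-variate arterial input function with per-voxel
  exponential residue functions scaled by pulmonary blood flow (PBF).

All anatomy and parameter texture are analytic functions of physical (mm)
coordinates, so the same subject can be rasterized consistently on the
(coarser, 2D) UTE grid and the (3D) DCE grid.  Perfusion-defect regions are
unions of ellipsoidal blobs; inside them PBF is scaled down and the
compartment T1s are shortened, giving the coupled structure (low flow with
short T1) the downstream statistics are designed to detect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .grid import ImageGrid

# Echo times of the multi-echo UTE acquisition (microseconds).
DEFAULT_TE_US: tuple[float, ...] = (70.0, 500.0, 1200.0, 1650.0, 2300.0)

# Inversion-time frames of the sliding-window reconstruction (ms): spokes of
# all inversion blocks sorted by TI, windowed 120 wide / 60 step at TR 5 ms
# with 50% respiratory gating -> 60 ms windows every 30 ms.
DEFAULT_TI_MS: tuple[float, ...] = tuple(float(t) for t in range(30, 1471, 30))

DEFAULT_DCE_DT_S = 1.7
DEFAULT_DCE_FRAMES = 20

# Anatomical reference frame (mm): UTE field of view 500 x 500, torso centred.
FOV_UTE_MM = (500.0, 500.0)
FOV_DCE_MM = (366.0, 450.0)


def default_ute_grid(n: int = 64) -> ImageGrid:
    """Coronal 2D UTE grid (row = head-foot, col = left-right)."""
    return ImageGrid(shape=(n, n), spacing=(FOV_UTE_MM[0] / n, FOV_UTE_MM[1] / n), origin=(0.0, 0.0))


def default_dce_grid(nz: int = 16, ny: int = 52, nx: int = 64) -> ImageGrid:
    """3D DCE grid: 5 mm slices centred on the lungs, own FoV and origin."""
    sy = FOV_DCE_MM[0] / ny
    sx = FOV_DCE_MM[1] / nx
    oz = -0.5 * nz * 5.0
    oy = 0.5 * FOV_UTE_MM[0] - 0.5 * FOV_DCE_MM[0]
    ox = 0.5 * FOV_UTE_MM[1] - 0.5 * FOV_DCE_MM[1]
    return ImageGrid(shape=(nz, ny, nx), spacing=(5.0, sy, sx), origin=(oz, oy, ox))


@dataclass(frozen=True)
class AIFParams:
    """Gamma-variate arterial input function, c(t) = a·(τ/αβ)^α·e^{α−τ/β}."""

    amplitude: float = 4.0       # peak concentration, relative-enhancement units
    onset_s: float = 3 * DEFAULT_DCE_DT_S
    shape: float = 3.0           # α
    scale_s: float = 1.5         # β


@dataclass(frozen=True)
class PhantomParams:
    """Tissue/acquisition parameters of one synthetic subject.

    Compartment constants follow 1.5 T lung literature scales: blood T1 near
    1400 ms with long T2*, parenchymal tissue T1 near 1100 ms with sub-ms
    T2*. The defect alterations are the study conditions of the coupled
    cohort: observed T1 scaled by ``defect_t1_scale`` (both compartments)
    and PBF scaled by ``defect_pbf_scale``.
    """

    defect_fraction: float = 0.2
    f_blood: float = 0.25
    t1_blood_ms: float = 1400.0
    t1_tissue_ms: float = 1100.0
    t2s_blood_us: float = 50_000.0
    t2s_tissue_us: float = 700.0
    pd_lung: float = 0.30
    pd_body: float = 1.0
    body_t1_ms: float = 600.0
    body_t2s_us: float = 30_000.0
    pbf_normal: float = 0.04          # 1/s (raw deconvolution units)
    mtt_s: float = 6.0
    defect_t1_scale: float = 0.85
    defect_pbf_scale: float = 0.2
    pbf_texture_amp: float = 0.25
    t1_texture_amp: float = 0.05
    noise_sigma: float = 0.0
    aif: AIFParams = field(default_factory=AIFParams)
    inversion_efficiency: float = 2.0  # B/A of the IR signal model


@dataclass
class _Ellipsoid:
    center: tuple[float, float, float]  # (z, y, x) mm
    radii: tuple[float, float, float]   # semi-axes, mm; np.inf => cylinder axis

    def inside(self, z, y, x):
        q = 0.0
        for c, r, v in zip(self.center, self.radii, (z, y, x)):
            if np.isfinite(r):
                q = q + ((v - c) / r) ** 2
        return q <= 1.0


@dataclass
class LungGeometry:
    """Analytic anatomy in absolute mm coordinates (z, y, x)."""

    torso: _Ellipsoid
    lung_left: _Ellipsoid
    lung_right: _Ellipsoid
    artery: _Ellipsoid
    defect_blobs: list[_Ellipsoid] = field(default_factory=list)
    texture_coeffs: np.ndarray | None = None  # rows (a, fz?, fy, fx, phase)
    texture_norm: tuple[float, float] = (0.0, 1.0)
    slice_z_mm: float = 0.0

    # -- rasterizers ------------------------------------------------------
    def _coords(self, grid: ImageGrid):
        cs = grid.coords_mm()
        if grid.ndim == 2:
            y, x = cs
            z = np.asarray(self.slice_z_mm)
            return z, y, x
        return cs[0], cs[1], cs[2]

    def lung_labels(self, grid: ImageGrid) -> np.ndarray:
        """0 background, 1 left lung (smaller x), 2 right lung."""
        z, y, x = self._coords(grid)
        lab = np.zeros(grid.shape, dtype=np.uint8)
        lab[np.broadcast_to(self.lung_left.inside(z, y, x), grid.shape)] = 1
        lab[np.broadcast_to(self.lung_right.inside(z, y, x), grid.shape)] = 2
        return lab

    def body_mask(self, grid: ImageGrid) -> np.ndarray:
        z, y, x = self._coords(grid)
        return np.broadcast_to(self.torso.inside(z, y, x), grid.shape).copy()

    def artery_mask(self, grid: ImageGrid) -> np.ndarray:
        z, y, x = self._coords(grid)
        return np.broadcast_to(self.artery.inside(z, y, x), grid.shape).copy()

    def defect_mask(self, grid: ImageGrid, blobs: list[_Ellipsoid] | None = None) -> np.ndarray:
        z, y, x = self._coords(grid)
        lung = self.lung_labels(grid) > 0
        out = np.zeros(grid.shape, dtype=bool)
        for b in self.defect_blobs if blobs is None else blobs:
            out |= np.broadcast_to(b.inside(z, y, x), grid.shape)
        return out & lung

    def texture(self, grid: ImageGrid) -> np.ndarray:
        """Smooth low-frequency field, ~unit std over the lungs, clipped ±2."""
        if self.texture_coeffs is None:
            return np.zeros(grid.shape)
        z, y, x = self._coords(grid)
        u = np.zeros(grid.shape)
        ly, lx = FOV_UTE_MM
        for a, fy, fx, ph in self.texture_coeffs:
            u = u + a * np.cos(2 * np.pi * (fy * y / ly + fx * x / lx) + ph)
        mu, sd = self.texture_norm
        return np.clip((u - mu) / sd, -2.0, 2.0)


@dataclass
class PhantomTruth:
    """Ground truth on one grid: label/defect masks and per-voxel parameter
    fields, plus the scalar simulation parameters.

    The compartment relaxation entries are per-voxel maps (not scalars)
    because the defect alteration shortens both compartment T1s locally.
    """

    grid: ImageGrid
    label_map: np.ndarray            # 0 bg, 1 left, 2 right
    defect_mask: np.ndarray
    geometry: LungGeometry
    seed: int
    params: PhantomParams
    body_mask: np.ndarray | None = None
    artery_mask: np.ndarray | None = None
    pbf: np.ndarray | None = None            # 1/s, 0 outside lungs
    f_blood: np.ndarray | None = None
    f_tissue: np.ndarray | None = None
    t1_blood_ms_map: np.ndarray | None = None
    t1_tissue_ms_map: np.ndarray | None = None
    t2s_tissue_us_map: np.ndarray | None = None
    pd: np.ndarray | None = None

    @property
    def lung_mask(self) -> np.ndarray:
        return self.label_map > 0

    def achieved_defect_fraction(self) -> float:
        n_lung = int(self.lung_mask.sum())
        return float(self.defect_mask.sum()) / n_lung if n_lung else 0.0


@dataclass
class TISeries:
    """Stack of 2D images indexed by inversion time at one echo time."""

    te_us: float
    tis_ms: np.ndarray
    data: np.ndarray                 # (nTI, rows, cols)
    grid: ImageGrid
    slice_thickness_mm: float = 15.0
    slice_position_mm: float = 0.0

    def __post_init__(self):
        self.tis_ms = np.asarray(self.tis_ms, dtype=float)
        if self.tis_ms.ndim != 1 or len(self.tis_ms) != self.data.shape[0]:
            raise ValueError("need exactly one image per TI")
        if np.any(np.diff(self.tis_ms) <= 0):
            raise ValueError("TIs must be strictly increasing")


@dataclass
class DCESeries:
    """4D dynamic series: frames of a 3D volume at fixed interval."""

    data: np.ndarray                 # (T, nz, ny, nx)
    grid: ImageGrid                  # 3D spatial grid
    dt_s: float = DEFAULT_DCE_DT_S

    def __post_init__(self):
        if self.dt_s <= 0:
            raise ValueError("frame interval must be positive")
        if self.data.shape[0] < 3:
            raise ValueError("need at least 3 frames")
        if self.data.shape[1:] != self.grid.shape:
            raise ValueError("frame shape must match the grid")

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_s


# ---------------------------------------------------------------------------
# Construction

def _default_geometry(rng: np.random.Generator) -> LungGeometry:
    cy, cx = 0.5 * FOV_UTE_MM[0], 0.5 * FOV_UTE_MM[1]
    geo = LungGeometry(
        torso=_Ellipsoid((0.0, cy, cx), (np.inf, 210.0, 230.0)),
        lung_left=_Ellipsoid((0.0, cy, cx - 115.0), (150.0, 145.0, 72.0)),
        lung_right=_Ellipsoid((0.0, cy, cx + 115.0), (150.0, 145.0, 72.0)),
        artery=_Ellipsoid((0.0, cy, cx), (np.inf, 18.0, 18.0)),
    )
    k = 8
    coeffs = np.column_stack([
        rng.normal(0.0, 1.0, k),            # amplitude
        rng.uniform(0.5, 2.0, k) * rng.choice([-1, 1], k),   # cycles along y
        rng.uniform(0.5, 2.0, k) * rng.choice([-1, 1], k),   # cycles along x
        rng.uniform(0.0, 2 * np.pi, k),     # phase
    ])
    geo.texture_coeffs = coeffs
    # normalize the raw field to ~zero mean / unit std over the lung interior
    probe = ImageGrid(shape=(96, 96), spacing=(FOV_UTE_MM[0] / 96, FOV_UTE_MM[1] / 96))
    y, x = probe.coords_mm()
    u = np.zeros(probe.shape)
    for a, fy, fx, ph in coeffs:
        u = u + a * np.cos(2 * np.pi * (fy * y / FOV_UTE_MM[0] + fx * x / FOV_UTE_MM[1]) + ph)
    lung = geo.lung_labels(probe) > 0
    geo.texture_norm = (float(u[lung].mean()), float(u[lung].std() + 1e-12))
    return geo


def _calibrate_defects(
    geo: LungGeometry,
    grid: ImageGrid,
    target: float,
    rng: np.random.Generator,
    band: float = 0.005,
    max_blobs: int = 300,
) -> list[_Ellipsoid]:
    """Grow a union of ellipsoidal blobs inside the lungs until the lung
    voxel fraction on ``grid`` reaches ``target`` (within ``band``)."""
    lung = geo.lung_labels(grid) > 0
    n_lung = int(lung.sum())
    if n_lung == 0:
        raise ValueError("empty lung mask; cannot place defects")
    if target <= 0:
        return []
    if grid.ndim == 2:
        zc, yc, xc = np.full(n_lung, geo.slice_z_mm), *[
            c[lung] for c in np.meshgrid(*[
                grid.origin[a] + (np.arange(grid.shape[a]) + 0.5) * grid.spacing[a]
                for a in range(2)], indexing="ij")
        ]
    else:
        zz, yy, xx = np.meshgrid(*[
            grid.origin[a] + (np.arange(grid.shape[a]) + 0.5) * grid.spacing[a]
            for a in range(3)], indexing="ij")
        zc, yc, xc = zz[lung], yy[lung], xx[lung]

    blobs: list[_Ellipsoid] = []
    mask = np.zeros(grid.shape, dtype=bool)
    h = geo.lung_left.radii[1]  # lung semi-height sets the blob scale
    for _ in range(max_blobs):
        frac = mask.sum() / n_lung
        if frac >= target - band:
            break
        i = int(rng.integers(0, n_lung))
        ry = rng.uniform(0.15, 0.45) * h
        rx = rng.uniform(0.6, 1.2) * ry
        rz = rng.uniform(0.6, 1.2) * ry
        blob = _Ellipsoid((float(zc[i]), float(yc[i]), float(xc[i])), (rz, ry, rx))
        cand = mask | geo.defect_mask(grid, [blob])
        if cand.sum() / n_lung <= target + band:
            blobs.append(blob)
            mask = cand
            continue
        # overshoot: bisect a scale on the blob radii to land inside the band
        lo, hi = 0.0, 1.0
        for _ in range(40):
            s = 0.5 * (lo + hi)
            sb = _Ellipsoid(blob.center, tuple(r * s for r in blob.radii))
            f = (mask | geo.defect_mask(grid, [sb])).sum() / n_lung
            if f < target - band:
                lo = s
            elif f > target + band:
                hi = s
            else:
                blobs.append(sb)
                mask |= geo.defect_mask(grid, [sb])
                break
        else:
            continue  # this blob cannot land in the band; try another
        break
    achieved = mask.sum() / n_lung
    if abs(achieved - target) > 0.02:
        raise ValueError(
            f"defect fraction {target:.3f} unreachable inside the lung mask: "
            f"achieved {achieved:.3f}"
        )
    return blobs


def make_lungs(
    grid: ImageGrid,
    defect_fraction: float = 0.2,
    seed: int = 0,
    params: PhantomParams | None = None,
) -> PhantomTruth:
    """Generate lung label map and defect mask (geometry only).

    Two disjoint elliptical lungs left/right of the midline inside a torso;
    the defect mask is a union of seeded ellipsoidal blobs occupying
    ``defect_fraction`` of the lung voxels on ``grid`` (within ±2
    percentage points, typically much closer).
    """
    if not 0.0 <= defect_fraction <= 0.9:
        raise ValueError(f"defect fraction must be in [0, 0.9], got {defect_fraction}")
    params = params or PhantomParams(defect_fraction=defect_fraction)
    rng = np.random.default_rng(seed)
    geo = _default_geometry(rng)
    geo.defect_blobs = _calibrate_defects(geo, grid, defect_fraction, rng)
    return PhantomTruth(
        grid=grid,
        label_map=geo.lung_labels(grid),
        defect_mask=geo.defect_mask(grid),
        geometry=geo,
        seed=int(seed),
        params=params,
        body_mask=geo.body_mask(grid),
        artery_mask=geo.artery_mask(grid),
    )


def _fill_fields(truth: PhantomTruth) -> PhantomTruth:
    p = truth.params
    grid = truth.grid
    lung = truth.lung_mask
    defect = truth.defect_mask
    body = truth.body_mask & ~lung
    artery = truth.artery_mask & body
    u = truth.geometry.texture(grid)

    f_blood = np.zeros(grid.shape)
    f_blood[lung] = p.f_blood
    f_blood[artery] = 1.0
    t1_blood = np.full(grid.shape, p.t1_blood_ms)
    t1_tissue = np.full(grid.shape, p.body_t1_ms)
    t1_tissue[lung] = p.t1_tissue_ms * (1.0 + p.t1_texture_amp * u[lung])
    t1_blood[defect] *= p.defect_t1_scale
    t1_tissue[defect] *= p.defect_t1_scale
    t2s_tissue = np.full(grid.shape, p.body_t2s_us)
    t2s_tissue[lung] = p.t2s_tissue_us

    pbf = np.zeros(grid.shape)
    pbf[lung] = np.clip(p.pbf_normal * (1.0 + p.pbf_texture_amp * u[lung]), 0.05 * p.pbf_normal, None)
    pbf[defect] *= p.defect_pbf_scale

    pd = np.zeros(grid.shape)
    pd[body] = p.pd_body
    pd[lung] = p.pd_lung
    pd[artery] = p.pd_body

    truth.f_blood = f_blood
    truth.f_tissue = np.where(pd > 0, 1.0 - f_blood, 0.0)
    truth.t1_blood_ms_map = t1_blood
    truth.t1_tissue_ms_map = t1_tissue
    truth.t2s_tissue_us_map = t2s_tissue
    truth.pbf = pbf
    truth.pd = pd
    return truth


def make_phantom(
    grid: ImageGrid,
    params: PhantomParams | None = None,
    seed: int = 0,
) -> PhantomTruth:
    """Full phantom truth: anatomy plus all per-voxel parameter fields."""
    params = params or PhantomParams()
    truth = make_lungs(grid, params.defect_fraction, seed=seed, params=params)
    return _fill_fields(truth)


def truth_on_grid(truth: PhantomTruth, grid: ImageGrid, slice_z_mm: float | None = None) -> PhantomTruth:
    """Rasterize the same subject (geometry, parameters, seed) on another grid."""
    geo = truth.geometry
    if slice_z_mm is not None and grid.ndim == 2:
        geo = dataclasses.replace(geo)
        geo.slice_z_mm = float(slice_z_mm)
    out = PhantomTruth(
        grid=grid,
        label_map=geo.lung_labels(grid),
        defect_mask=geo.defect_mask(grid),
        geometry=geo,
        seed=truth.seed,
        params=truth.params,
        body_mask=geo.body_mask(grid),
        artery_mask=geo.artery_mask(grid),
    )
    return _fill_fields(out)


# ---------------------------------------------------------------------------
# Forward models

def _compartment_weights(truth: PhantomTruth, te_us: float):
    p = truth.params
    w_b = truth.f_blood * np.exp(-te_us / p.t2s_blood_us)
    w_t = truth.f_tissue * np.exp(-np.divide(te_us, truth.t2s_tissue_us_map,
                                             out=np.full(truth.grid.shape, np.inf),
                                             where=truth.t2s_tissue_us_map > 0))
    return w_b, w_t


def observed_t1(truth: PhantomTruth, te_us: float) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth observed T1 at echo time ``te_us``.

    T1_obs = (w_b·T1_blood + w_t·T1_tissue) / (w_b + w_t) with
    w_i = f_i·exp(−TE/T2*_i).  Returns ``(map_ms, valid)`` defined on lung
    voxels only (NaN elsewhere); voxels whose total weight underflows are
    flagged invalid.
    """
    if te_us < 0:
        raise ValueError("TE must be nonnegative")
    w_b, w_t = _compartment_weights(truth, te_us)
    wsum = w_b + w_t
    lung = truth.lung_mask
    valid = lung & (wsum > 0)
    out = np.full(truth.grid.shape, np.nan)
    out[valid] = (
        w_b[valid] * truth.t1_blood_ms_map[valid]
        + w_t[valid] * truth.t1_tissue_ms_map[valid]
    ) / wsum[valid]
    return out, valid


def _t1_everywhere(truth: PhantomTruth, te_us: float):
    """Observed T1 and equilibrium signal A for every material voxel."""
    w_b, w_t = _compartment_weights(truth, te_us)
    wsum = w_b + w_t
    a_map = truth.pd * wsum
    t1 = np.full(truth.grid.shape, np.nan)
    ok = (wsum > 0) & (truth.pd > 0)
    t1[ok] = (
        w_b[ok] * truth.t1_blood_ms_map[ok] + w_t[ok] * truth.t1_tissue_ms_map[ok]
    ) / wsum[ok]
    return t1, a_map


def lung_signal_amplitude(truth: PhantomTruth, te_us: float = DEFAULT_TE_US[0]) -> float:
    """Mean equilibrium lung signal A at ``te_us`` — the SNR reference."""
    _, a_map = _t1_everywhere(truth, te_us)
    return float(a_map[truth.lung_mask].mean())


def sigma_for_snr(truth: PhantomTruth, snr: float, te_us: float = DEFAULT_TE_US[0]) -> float:
    return lung_signal_amplitude(truth, te_us) / snr if snr > 0 else 0.0


def simulate_ir_series(
    truth: PhantomTruth,
    te_list_us=DEFAULT_TE_US,
    ti_list_ms=DEFAULT_TI_MS,
    sigma: float = 0.0,
    seed: int = 0,
    slice_thickness_mm: float = 15.0,
) -> list[TISeries]:
    """Simulate magnitude IR series per echo time.

    S(TI) = |A − B·exp(−TI/T1_obs(TE))| + N(0, σ) with A = PD·Σw_i and
    B = inversion_efficiency·A.  Voxels without material (air) get noise
    only.  Seeded generation is bit-reproducible.
    """
    if sigma < 0:
        raise ValueError("noise sigma must be nonnegative")
    tis = np.asarray(ti_list_ms, dtype=float)
    if tis.size == 0 or np.any(np.diff(tis) <= 0):
        raise ValueError("TI list must be nonempty and strictly ascending")
    rng = np.random.default_rng(seed)
    inv_eff = truth.params.inversion_efficiency
    out = []
    for te in te_list_us:
        t1, a_map = _t1_everywhere(truth, te)
        a = np.nan_to_num(a_map)
        decay = np.zeros((len(tis),) + truth.grid.shape)
        ok = np.isfinite(t1) & (t1 > 0)
        decay[:, ok] = np.exp(-tis[:, None] / t1[ok][None, :])
        s = np.abs(a[None] - inv_eff * a[None] * decay)
        s[:, ~ok] = 0.0
        if sigma > 0:
            s = s + rng.normal(0.0, sigma, s.shape)
        out.append(
            TISeries(
                te_us=float(te), tis_ms=tis, data=s, grid=truth.grid,
                slice_thickness_mm=slice_thickness_mm,
                slice_position_mm=truth.geometry.slice_z_mm,
            )
        )
    return out


def gamma_variate(times_s: np.ndarray, aif: AIFParams) -> np.ndarray:
    """AIF samples at ``times_s``; zero before onset, peak ``amplitude``."""
    tau = np.asarray(times_s, dtype=float) - aif.onset_s
    peak = aif.shape * aif.scale_s
    out = np.zeros_like(tau)
    pos = tau > 0
    out[pos] = aif.amplitude * (tau[pos] / peak) ** aif.shape * np.exp(
        aif.shape - tau[pos] / aif.scale_s
    )
    return out


def simulate_dce(
    truth: PhantomTruth,
    dt_s: float = DEFAULT_DCE_DT_S,
    n_frames: int = DEFAULT_DCE_FRAMES,
    sigma: float = 0.0,
    seed: int = 0,
) -> tuple[DCESeries, np.ndarray]:
    """Simulate the DCE series; returns ``(series, true_aif)``.

    Tissue concentration is the discrete convolution
    C_v(t_j) = Δt·Σ_{k≤j} AIF(t_k)·PBF_v·exp(−(t_j−t_k)/MTT); artery voxels
    carry the AIF itself (≈10× the tissue amplitude).  Signal is
    S = S0·(1 + C) + noise with S0 the proton-density map.
    """
    if dt_s <= 0:
        raise ValueError("frame interval must be positive")
    if n_frames < 3:
        raise ValueError("need at least 3 frames")
    if sigma < 0:
        raise ValueError("noise sigma must be nonnegative")
    p = truth.params
    times = np.arange(n_frames) * dt_s
    if p.aif.onset_s >= times[-1]:
        raise ValueError(
            f"AIF onset {p.aif.onset_s:.2f}s beyond last frame {times[-1]:.2f}s"
        )
    aif = gamma_variate(times, p.aif)
    residue = np.exp(-times / p.mtt_s)
    kern = dt_s * np.convolve(aif, residue)[:n_frames]   # Δt·Σ aif(k)·R(t−k)
    lung = truth.lung_mask
    artery = truth.artery_mask & (truth.pd > 0) & ~lung
    conc = np.zeros((n_frames,) + truth.grid.shape)
    conc[:, lung] = kern[:, None] * truth.pbf[lung][None, :]
    conc[:, artery] = aif[:, None]
    s0 = truth.pd
    s = s0[None] * (1.0 + conc)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        s = s + rng.normal(0.0, sigma, s.shape)
    return DCESeries(data=s, grid=truth.grid, dt_s=dt_s), aif
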