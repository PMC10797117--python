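"""End-to-end orchestration: subject pipeline and cohort statistics.

A "subject" is one synthetic patient: 1-2 coronal UTE slices (IR series at
five echo times) plus one 4D DCE volume, all rasterized from the same
analytic phantom.  ``run_subject`` chains T1 mapping, perfusion
quantification, both correspondence routes and the per-subject statistics;
``run_cohort`` generates a coupled cohort and computes the inter-patient
statistics.

Cohort coupling follows a single latent severity per subject: more severe
disease means a larger perfusion-defect fraction, globally shorter tissue
T1 and lower normal-region blood flow.  This produces the sign structure
the analysis is designed to detect (T1 correlating positively with PBF and
negatively with QDP across patients, defect voxels shorter than normal
voxels within patients).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correspondence as corr
from . import dce_perfusion as dce
from . import phantom as ph
from . import stats as st
from .grid import ImageGrid
from .io import write_nifti
from .t1_mapping import T1Map, map_t1


@dataclass
class RunConfig:
    """Validated, serializable configuration of a pipeline run."""

    te_list_us: tuple[float, ...] = ph.DEFAULT_TE_US
    ti_list_ms: tuple[float, ...] = ph.DEFAULT_TI_MS
    ute_matrix: int = 64
    dce_shape: tuple[int, int, int] = (16, 52, 64)
    slice_positions_mm: tuple[float, ...] = (0.0, 30.0)
    dce_dt_s: float = 1.7
    dce_frames: int = 20
    n_baseline: int = 3
    snr: float = 20.0                      # 0 => noiseless
    svd_lambda: float = 0.15
    otsu_bins: int = 256
    n_strips: int = 10
    n_blocks: int = 10
    aif_percentile: float = 99.0
    aif_top_n: int = 20
    aif_floor: float = 0.2
    seg_tolerance: float = 0.1
    pbf_scale: float = 6000.0
    seed: int = 0
    # cohort severity model: parameter = base - slope * severity (+ noise)
    sev_defect_base: float = 0.05
    sev_defect_slope: float = 0.50
    sev_t1_base_ms: float = 1250.0
    sev_t1_slope_ms: float = 250.0
    sev_t1_sd_ms: float = 50.0
    sev_pbf_base: float = 0.05
    sev_pbf_slope: float = 0.5
    sev_pbf_lognorm_sd: float = 0.15
    single_slice_fraction: float = 4.0 / 22.0

    def __post_init__(self):
        self.te_list_us = tuple(float(t) for t in self.te_list_us)
        self.ti_list_ms = tuple(float(t) for t in self.ti_list_ms)
        self.slice_positions_mm = tuple(float(z) for z in self.slice_positions_mm)
        self.dce_shape = tuple(int(s) for s in self.dce_shape)
        checks = [
            (len(self.te_list_us) >= 1, "need at least one echo time"),
            (len(self.ti_list_ms) >= 3, "need at least 3 inversion times"),
            (self.ute_matrix >= 16, "UTE matrix too small"),
            (self.dce_shape[0] >= 3, "need at least 3 DCE slices"),
            (self.dce_dt_s > 0, "DCE frame interval must be positive"),
            (self.dce_frames >= 3, "need at least 3 DCE frames"),
            (1 <= self.n_baseline < self.dce_frames, "invalid baseline frame count"),
            (0.0 < self.svd_lambda < 1.0, "svd_lambda must be in (0,1)"),
            (self.otsu_bins >= 8, "need at least 8 histogram bins"),
            (self.snr >= 0, "SNR must be nonnegative"),
            (self.n_strips >= 1 and self.n_blocks >= 1, "invalid subdivision counts"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(_plain(dataclasses.asdict(self)), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def ute_grid(self) -> ImageGrid:
        return ph.default_ute_grid(self.ute_matrix)

    def dce_grid(self) -> ImageGrid:
        return ph.default_dce_grid(*self.dce_shape)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class SliceData:
    z_mm: float
    series: list[ph.TISeries]              # one per TE
    truth: ph.PhantomTruth | None = None


@dataclass
class SubjectData:
    subject_id: int
    dce_series: ph.DCESeries
    dce_segmentation: np.ndarray           # lung label map on the DCE grid
    dce_body_mask: np.ndarray
    slices: list[SliceData]
    truth: ph.PhantomTruth | None = None   # DCE-grid truth (phantom subjects)
    aif_true: np.ndarray | None = None
    deformation: corr.DeformationField | None = None   # None => identity
    severity: float | None = None


def make_subject(config: RunConfig, seed: int, subject_id: int = 0,
                 severity: float | None = None, n_slices: int | None = None,
                 params: ph.PhantomParams | None = None) -> SubjectData:
    """Generate one synthetic subject.

    With ``severity`` s in [0, 1] the phantom parameters follow the cohort
    coupling model; an explicit ``params`` overrides it (severity then only
    tags the subject).
    """
    rng = np.random.default_rng(seed)
    if params is None:
        s = float(rng.uniform(0.0, 1.0)) if severity is None else float(severity)
        severity = s
        params = ph.PhantomParams(
            defect_fraction=config.sev_defect_base + config.sev_defect_slope * s,
            t1_tissue_ms=config.sev_t1_base_ms - config.sev_t1_slope_ms * s
            + float(rng.normal(0.0, config.sev_t1_sd_ms)),
            pbf_normal=config.sev_pbf_base * (1.0 - config.sev_pbf_slope * s)
            * float(rng.lognormal(0.0, config.sev_pbf_lognorm_sd)),
        )
    dce_grid = config.dce_grid()
    truth = ph.make_phantom(dce_grid, params=params, seed=int(seed))

    snr = config.snr
    sigma_dce = params.pd_lung / snr if snr > 0 else 0.0
    series_dce, aif_true = ph.simulate_dce(
        truth, dt_s=config.dce_dt_s, n_frames=config.dce_frames,
        sigma=sigma_dce, seed=int(seed) + 1,
    )

    if n_slices is None:
        n_slices = len(config.slice_positions_mm)
    slices = []
    for j, z in enumerate(config.slice_positions_mm[:n_slices]):
        ute_truth = ph.truth_on_grid(truth, config.ute_grid(), slice_z_mm=z)
        sigma_ir = ph.sigma_for_snr(ute_truth, snr) if snr > 0 else 0.0
        ser = ph.simulate_ir_series(
            ute_truth, te_list_us=config.te_list_us, ti_list_ms=config.ti_list_ms,
            sigma=sigma_ir, seed=int(seed) + 10 + j,
        )
        slices.append(SliceData(z_mm=z, series=ser, truth=ute_truth))
    return SubjectData(
        subject_id=subject_id, dce_series=series_dce,
        dce_segmentation=truth.label_map, dce_body_mask=truth.body_mask,
        slices=slices, truth=truth, aif_true=aif_true, severity=severity,
    )


def _segment_ute_slice(config: RunConfig, sl: SliceData) -> np.ndarray:
    """Region-grow the lungs on the longest-TI image of the TE3 series and
    split left/right.  Seeds default to the truth lung centroids."""
    te_idx = min(2, len(sl.series) - 1)
    img = sl.series[te_idx].data[-1]
    if sl.truth is not None:
        from scipy import ndimage

        seeds = [tuple(int(round(c)) for c in
                       ndimage.center_of_mass(sl.truth.label_map == lab))
                 for lab in (1, 2)]
    else:
        raise ValueError("no truth available to seed the segmentation")
    mask = corr.region_grow_segment(img, seeds, tolerance=config.seg_tolerance)
    return corr.split_left_right(mask)


def _dce_slab_grid(dce_grid: ImageGrid) -> ImageGrid:
    return ImageGrid(shape=dce_grid.shape[1:], spacing=dce_grid.spacing[1:],
                     origin=dce_grid.origin[1:])


@dataclass
class SubjectResult:
    subject_id: int
    summary: dict
    t1_maps: list[list[T1Map]] = field(default_factory=list)   # [slice][te]
    pbf_map: dce.PBFMap | None = None
    classification: dce.DefectClassification | None = None
    residuals_tmax: np.ndarray | None = None
    subdivisions: list[dict] = field(default_factory=list)
    area_table: pd.DataFrame | None = None


def run_subject(config: RunConfig, subject: SubjectData) -> SubjectResult:
    """Run the full per-subject pipeline; deterministic given config+data."""
    te_list = config.te_list_us
    n_te = len(te_list)
    dce_grid = subject.dce_series.grid
    stage = "signal-to-concentration"
    try:
        conc = dce.to_concentration(subject.dce_series, n_baseline=config.n_baseline)
        stage = "AIF detection"
        aif = dce.detect_aif(conc, subject.dce_body_mask,
                             percentile=config.aif_percentile,
                             top_n=config.aif_top_n, floor=config.aif_floor)
        stage = "deconvolution"
        resid = dce.deconvolve(conc, aif, subject.dce_segmentation,
                               svd_lambda=config.svd_lambda)
        pbf3d = dce.compute_pbf(resid)
        t_max = dce.find_tmax(resid)
        stage = "defect classification"
        lung3d = subject.dce_segmentation > 0
        thresholds = dce.otsu_two_thresholds(resid.data[t_max][lung3d & resid.mask],
                                             n_bins=config.otsu_bins)
        cls3d = dce.classify_defects(resid, t_max, thresholds,
                                     subject.dce_segmentation)
    except Exception as err:
        raise RuntimeError(
            f"subject {subject.subject_id}: stage '{stage}' failed: {err}"
        ) from err

    slab_grid = _dce_slab_grid(dce_grid)
    ute_grid = config.ute_grid()

    # pooled-across-slice accumulators
    t1_values: list[list[np.ndarray]] = [[] for _ in range(n_te)]
    reg_pairs: list[list[tuple[np.ndarray, np.ndarray]]] = [[] for _ in range(n_te)]
    cls_pairs: list[list[tuple[np.ndarray, np.ndarray]]] = [[] for _ in range(n_te)]
    sub_t1: list[list[np.ndarray]] = [[] for _ in range(n_te)]
    sub_pbf: list[np.ndarray] = []
    sub_defect_frac: list[np.ndarray] = []
    pbf_slab_values: list[np.ndarray] = []
    qdp_slab_counts = np.zeros(2)          # defect, lung
    area_rows = []

    result = SubjectResult(subject_id=subject.subject_id, summary={},
                           pbf_map=pbf3d, classification=cls3d,
                           residuals_tmax=resid.data[t_max])

    for si, sl in enumerate(subject.slices):
        stage = f"slice {si}: segmentation"
        try:
            seg = _segment_ute_slice(config, sl)
            stage = f"slice {si}: T1 mapping"
            maps = [map_t1(sl.series[k], seg) for k in range(n_te)]
            stage = f"slice {si}: slab projection"
            slab_pbf, _ = dce.project_to_slab(pbf3d.pbf, dce_grid, sl.z_mm)
            slab_labels, _ = dce.project_to_slab(cls3d.labels, dce_grid, sl.z_mm,
                                                 is_label=True)
            stage = f"slice {si}: registration correspondence"
            fld = subject.deformation or corr.identity_field(slab_grid, ute_grid)
            warped_pbf = corr.apply_deformation(slab_pbf, slab_grid, fld, "linear")
            warped_labels = corr.apply_deformation(slab_labels, slab_grid, fld,
                                                   "nearest")
            stage = f"slice {si}: subdivision correspondence"
            slab_lung = slab_labels > 0
            slab_sides = corr.split_left_right(slab_lung)
            subs = {}
            for side in (1, 2):
                subs[("ute", side)] = corr.subdivide_lung(
                    seg == side, config.n_strips, config.n_blocks, ute_grid)
                subs[("dce", side)] = corr.subdivide_lung(
                    slab_sides == side, config.n_strips, config.n_blocks, slab_grid)
        except Exception as err:
            raise RuntimeError(
                f"subject {subject.subject_id}: stage '{stage}' failed: {err}"
            ) from err

        result.t1_maps.append(maps)
        result.subdivisions.append({f"{k[0]}_{k[1]}": v.area_ids for k, v in subs.items()})
        ute_lung = seg > 0
        warped_lung = warped_labels > 0
        slab_in_lung = slab_lung & np.isfinite(slab_pbf)
        pbf_slab_values.append(slab_pbf[slab_in_lung])
        qdp_slab_counts += (float((slab_labels == 2).sum()), float(slab_lung.sum()))

        for k in range(n_te):
            valid = maps[k].valid
            t1_values[k].append(maps[k].t1_ms[ute_lung & valid])
            sel = ute_lung & valid & warped_lung & np.isfinite(warped_pbf)
            reg_pairs[k].append((maps[k].t1_ms[sel], warped_pbf[sel]))
            selc = ute_lung & valid & warped_lung
            cls_pairs[k].append((maps[k].t1_ms[selc], warped_labels[selc]))

        # per-area medians, both lungs
        for side in (1, 2):
            sub_u, sub_d = subs[("ute", side)], subs[("dce", side)]
            for s, b in corr.corresponding_areas(sub_u, sub_d):
                am_u = sub_u.area_mask(s, b)
                am_d = sub_d.area_mask(s, b)
                pbf_area = slab_pbf[am_d]
                pbf_med = float(np.nanmedian(pbf_area)) if np.isfinite(pbf_area).any() else np.nan
                dfrac = float((slab_labels[am_d] == 2).mean())
                t1_meds = []
                for k in range(n_te):
                    vals = maps[k].t1_ms[am_u & maps[k].valid]
                    t1_meds.append(float(np.median(vals)) if len(vals) else np.nan)
                    sub_t1[k].append(np.array([t1_meds[-1]]))
                sub_pbf.append(np.array([pbf_med]))
                sub_defect_frac.append(np.array([dfrac]))
                area_rows.append({
                    "slice": si, "side": side, "strip": s, "block": b,
                    "pbf_median": pbf_med, "defect_fraction": dfrac,
                    **{f"t1_te{k + 1}_ms": t1_meds[k] for k in range(n_te)},
                })

    # ---- per-subject statistics ------------------------------------------
    summary: dict = {
        "subject_id": subject.subject_id,
        "severity": subject.severity,
        "n_slices": len(subject.slices),
        "t_max_frame": int(cls3d.t_max),
        "otsu_theta_low": cls3d.theta_low,
        "otsu_theta_high": cls3d.theta_high,
        "qdp_whole_lung_percent": cls3d.qdp_percent,
        "qdp_percent": 100.0 * qdp_slab_counts[0] / qdp_slab_counts[1]
        if qdp_slab_counts[1] else np.nan,
        "aif_n_voxels": aif.n_voxels,
        "aif_peak_frame": aif.peak_frame,
        "n_clamped_pbf": pbf3d.n_clamped,
        "median_pbf": float(np.median(np.concatenate(pbf_slab_values))
                            * config.pbf_scale) if pbf_slab_values else np.nan,
    }
    pooled_sub_pbf = np.concatenate(sub_pbf) if sub_pbf else np.array([])
    pooled_sub_dfrac = np.concatenate(sub_defect_frac) if sub_defect_frac else np.array([])
    for k in range(n_te):
        te_tag = f"te{k + 1}"
        pooled_t1 = np.concatenate(t1_values[k]) if t1_values[k] else np.array([])
        summary[f"median_t1_{te_tag}_ms"] = float(np.median(pooled_t1)) \
            if len(pooled_t1) else np.nan
        summary[f"n_valid_t1_{te_tag}"] = int(len(pooled_t1))

        x = np.concatenate([p[0] for p in reg_pairs[k]])
        y = np.concatenate([p[1] for p in reg_pairs[k]])
        try:
            res = st.spearman(x, y, kind="regPBF", te_us=te_list[k])
            summary[f"rho_regpbf_{te_tag}"] = res.rho
            summary[f"rho_regpbf_{te_tag}_p"] = res.p_value
            summary[f"rho_regpbf_{te_tag}_n"] = res.n
        except ValueError:
            summary[f"rho_regpbf_{te_tag}"] = np.nan

        t1m = np.concatenate([p[0] for p in cls_pairs[k]])
        lbl = np.concatenate([p[1] for p in cls_pairs[k]])
        cmp_res = st.defect_normal_comparison(
            t1m, np.ones_like(t1m, dtype=bool), lbl, te_us=te_list[k])
        summary[f"delta_t1_{te_tag}_percent"] = cmp_res.delta_t1_percent
        summary[f"median_t1_normal_{te_tag}_ms"] = cmp_res.median_t1_normal_ms
        summary[f"median_t1_defect_{te_tag}_ms"] = cmp_res.median_t1_defect_ms
        summary[f"defect_direction_{te_tag}"] = cmp_res.direction
        summary[f"defect_p_{te_tag}"] = cmp_res.p_value

        pooled_sub_t1 = np.concatenate(sub_t1[k]) if sub_t1[k] else np.array([])
        try:
            res = st.local_correlation_subdivided(pooled_sub_t1, pooled_sub_pbf,
                                                  kind="subPBF", te_us=te_list[k])
            summary[f"rho_subpbf_{te_tag}"] = res.rho
            summary[f"rho_subpbf_{te_tag}_n"] = res.n
        except ValueError:
            summary[f"rho_subpbf_{te_tag}"] = np.nan
        try:
            res = st.local_correlation_subdivided(pooled_sub_t1, pooled_sub_dfrac,
                                                  kind="subQDP", te_us=te_list[k])
            summary[f"rho_subqdp_{te_tag}"] = np.nan if res.degenerate else res.rho
            summary[f"rho_subqdp_{te_tag}_degenerate"] = res.degenerate
        except ValueError:
            summary[f"rho_subqdp_{te_tag}"] = np.nan

    result.summary = summary
    result.area_table = pd.DataFrame(area_rows)
    return result


def save_subject(result: SubjectResult, subject: SubjectData,
                 config: RunConfig, out_dir) -> Path:
    """Write NIfTI maps, the per-area CSV and the JSON summary."""
    out = Path(out_dir) / f"subject_{result.subject_id:03d}"
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed,
            "subject_id": result.subject_id}
    dce_grid = subject.dce_series.grid
    write_nifti(out / "pbf.nii.gz", result.pbf_map.pbf, dce_grid,
                sidecar={**meta, "units": "1/s",
                         "pbf_scale_to_ml_100ml_min": config.pbf_scale})
    write_nifti(out / "defect_labels.nii.gz", result.classification.labels,
                dce_grid, sidecar={**meta, "qdp_whole_lung_percent":
                                   result.classification.qdp_percent})
    write_nifti(out / "r_tmax.nii.gz", result.residuals_tmax, dce_grid,
                sidecar={**meta, "t_max_frame": result.classification.t_max})
    for si, maps in enumerate(result.t1_maps):
        for k, m in enumerate(maps):
            write_nifti(out / f"t1_slice{si}_te{k + 1}.nii.gz", m.t1_ms, m.grid,
                        sidecar={**meta, "te_us": m.te_us,
                                 "ti_list_ms": list(config.ti_list_ms)})
        for name, ids in result.subdivisions[si].items():
            write_nifti(out / f"subdivision_slice{si}_{name}.nii.gz",
                        ids.astype(np.int16),
                        config.ute_grid() if name.startswith("ute")
                        else _dce_slab_grid(dce_grid), sidecar=meta)
    result.area_table.to_csv(out / "areas.csv", index=False)
    (out / "summary.json").write_text(
        json.dumps(_plain(result.summary), indent=2, sort_keys=True,
                   allow_nan=True) + "\n")
    return out


def run_cohort(config: RunConfig, n_subjects: int = 22,
               seed: int | None = None, out_dir=None,
               ) -> tuple[pd.DataFrame, dict]:
    """Generate and analyse a cohort; returns (table, cohort statistics)."""
    if n_subjects < 3:
        raise ValueError("inter-patient correlations need at least 3 subjects")
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    n_single = int(round(config.single_slice_fraction * n_subjects))
    single_ids = set(rng.choice(n_subjects, size=n_single, replace=False).tolist())
    severities = rng.uniform(0.0, 1.0, n_subjects)

    rows = []
    for i in range(n_subjects):
        subj_seed = (seed * 100003 + i * 7919 + 1) % (2**31 - 1)
        n_slices = 1 if i in single_ids else len(config.slice_positions_mm)
        try:
            subject = make_subject(config, seed=subj_seed, subject_id=i,
                                   severity=float(severities[i]),
                                   n_slices=n_slices)
            result = run_subject(config, subject)
        except Exception as err:
            raise RuntimeError(f"subject {i} failed: {err}") from err
        if out_dir is not None:
            save_subject(result, subject, config, out_dir)
        rows.append(result.summary)
    table = pd.DataFrame(rows)
    stats = cohort_statistics(table, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "cohort_table.csv", index=False)
        (out / "cohort_stats.json").write_text(
            json.dumps(_plain(stats), indent=2, sort_keys=True,
                       allow_nan=True) + "\n")
        config.to_yaml(out / "config.yaml")
    return table, stats


def cohort_statistics(table: pd.DataFrame, config: RunConfig) -> dict:
    """Inter-patient correlations, Table-2-style local means, ΔT1 means."""
    te_list = config.te_list_us
    inter = st.interpatient_correlations(table, te_list)
    out: dict = {"n_subjects": int(len(table)), "config_hash": config.config_hash(),
                 "seed": config.seed}
    for i in range(1, len(te_list) + 1):
        for kind, key in (("IPBF", "rho_ipbf"), ("IQDP", "rho_iqdp")):
            res = inter[kind][i - 1]
            out[f"{key}_te{i}"] = res.rho if res else np.nan
            out[f"{key}_te{i}_p"] = res.p_value if res else np.nan
        for col, key in ((f"rho_regpbf_te{i}", f"rho_regpbf_te{i}"),
                         (f"rho_subpbf_te{i}", f"rho_subpbf_te{i}"),
                         (f"rho_subqdp_te{i}", f"rho_subqdp_te{i}")):
            m, sd, n = st.mean_sd_n(table[col]) if col in table else (np.nan, np.nan, 0)
            out[f"{key}_mean"] = m
            out[f"{key}_sd"] = sd
            out[f"{key}_n"] = n
        m, sd, n = st.mean_sd_n(table.get(f"delta_t1_te{i}_percent", []))
        out[f"delta_t1_te{i}_mean_percent"] = m
        out[f"delta_t1_te{i}_sd"] = sd
    # defect-shorter count at TE1 (raw median comparison)
    med_n = table.get("median_t1_normal_te1_ms")
    med_d = table.get("median_t1_defect_te1_ms")
    if med_n is not None and med_d is not None:
        both = np.isfinite(med_n) & np.isfinite(med_d)
        out["n_defect_shorter_te1"] = int((med_d[both] < med_n[both]).sum())
        out["n_evaluable_te1"] = int(both.sum())
    # correlation of local correlations with median T1(TE1)
    for col, kind in (("rho_regpbf_te1", "regcorr"), ("rho_subpbf_te1", "subcorr")):
        try:
            res = st.correlation_of_correlations(table["median_t1_te1_ms"],
                                                 table[col], kind=kind)
            out[f"rho_{kind}"] = res.rho
            out[f"rho_{kind}_p"] = res.p_value
        except (ValueError, KeyError):
            out[f"rho_{kind}"] = np.nan
    return out
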