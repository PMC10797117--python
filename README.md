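# lungt1dce

Quantitative lung MRI analysis pipeline: echo-time-dependent T1 mapping
from inversion-recovery UTE series, dynamic contrast-enhanced (DCE)
perfusion quantification, and the spatial-correspondence statistics that
relate the two — exercised end to end on a synthetic digital lung phantom
with known ground truth.

## The problem

In obstructive lung disease, regional perfusion is informative because
hypoxic vasoconstriction links it to ventilation, and vascular destruction
in emphysema produces perfusion defects. Two quantitative MRI readouts
probe this:

* **T1(TE)** — the longitudinal relaxation time observed when fitting
  inversion-recovery data acquired at ultra-short echo times. Each lung
  voxel mixes blood and extravascular protons with very different T2\*;
  as TE grows, the short-T2\* tissue signal decays away and the observed
  T1 drifts toward the blood value, so T1 becomes a TE-dependent
  composition probe that needs no contrast agent.
* **DCE perfusion** — pulmonary blood flow (PBF) from indicator-dilution
  deconvolution of contrast passage, and the perfusion-defect percentage
  (QDP) from histogram classification of the residue function.

This package implements both quantification chains and the statistics
connecting them (inter-patient and local Spearman correlations, Wilcoxon
defect/normal comparisons), together with a synthetic phantom that
generates both acquisitions from one ground truth so every stage is
testable without patient data.

## Models

**IR fitting.** Per voxel, the magnitude inversion-recovery model

    S(TI) = |A − B·exp(−TI / T1*)|,   T1 = T1*·(B/A − 1)

is solved by variable projection (A, B linear for fixed T1* and sign
pattern; golden-section refinement of T1*), with the Look-Locker
correction for continuous low-flip-angle sampling. The phantom's observed
T1 obeys the two-compartment weighting

    T1_obs(TE) = (w_b·T1_blood + w_t·T1_tissue) / (w_b + w_t),
    w_i = f_i·exp(−TE / T2*_i).

**Perfusion.** Tissue curves follow C = Δt·(AIF ⊛ PBF·R) with
R(τ) = exp(−τ/MTT). The pipeline inverts this per voxel by truncated-SVD
deconvolution (singular values below λ·σ_max zeroed, λ = 0.15 default)
after automatic AIF detection; PBF_v = max_t R_v(t); defect voxels are
those with R(t_max) below the lower of two Otsu thresholds;
QDP = 100·|defect|/|lung|. PBV = ΣC/ΣAIF and MTT = PBV/PBF complete the
central-volume set.

**Correspondence.** T1 and perfusion maps live on different grids; they
are matched either by applying a (precomputed or identity) deformation
field with pull-back resampling, or registration-free by subdividing each
lung into 10 vertical strips × 10 horizontal blocks of equal voxel count —
100 areas per lung that correspond by index across grids.

## Worked example

```python
from lungt1dce import PhantomParams
from lungt1dce.pipeline import RunConfig, make_subject, run_subject

cfg = RunConfig(snr=0.0, seed=1)                      # noiseless
subject = make_subject(cfg, seed=42,
                       params=PhantomParams(defect_fraction=0.20))
result = run_subject(cfg, subject)
print(result.summary["qdp_whole_lung_percent"])       # 20.29
print(result.summary["median_pbf"])                   # ≈ 211 mL/100mL/min
print(result.summary["rho_regpbf_te1"])               # ≈ 0.98
```

The subject carries a designed 20% perfusion defect; the recovered QDP of
20.3% equals the rasterized truth, the calibrated median PBF lands in the
physiological range, and the voxel-wise T1–PBF correlation is strongly
positive because defects couple low flow with short T1. The numbered
drivers under `analysis/` run the same computations as narrative analyses
(phantom construction, T1 recovery, perfusion recovery, local
correspondence, 22-subject cohort) and write their tables under
`results/`. The same pipeline is scriptable from the shell:

```bash
lungt1dce phantom make --size 64 --defect-fraction 0.2 --snr 20 --seed 1 --out scratch/phantom
lungt1dce cohort run --n-subjects 22 --seed 1 --out scratch/cohort
```

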