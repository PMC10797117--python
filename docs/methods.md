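# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the phantom-based validation does and does
not establish.

## Digital lung phantom

All anatomy is analytic in absolute millimetre coordinates: an elliptical
torso, two elliptical lungs left/right of the midline, a central arterial
blob, and perfusion-defect regions built from seeded ellipsoidal blobs.
Parameter texture is a seeded low-frequency Fourier field, normalized to
unit standard deviation over the lungs and clipped at ±2. Because
everything is a function of physical position, the same subject can be
rasterized consistently on the 2D UTE grid (500×500 mm field of view) and
the 3D DCE grid (366×450 mm in-plane, 5 mm slices) — the property the
registration-free subdivision statistics rely on.

Defect placement adds blobs until the requested lung-voxel fraction is
reached; the final blob's radii are bisected so the achieved fraction
lands within ±0.5 percentage points of the request (the contract allows
±2). An unreachable fraction raises an error naming the achieved value.

### Tissue model and defaults

| parameter | default | rationale |
|---|---|---|
| f_blood | 0.25 | capillary blood volume fraction of aerated parenchyma |
| T1 blood / tissue | 1400 / 1100 ms | 1.5 T literature scale |
| T2\* blood / tissue | 50 000 / 700 μs | long blood T2\*, sub-ms parenchymal T2\* |
| proton density lung / body | 0.30 / 1.00 | low parenchymal proton density |
| PBF (normal) | 0.04 s⁻¹ (≈240 mL/100 mL/min calibrated) | physiological pulmonary flow |
| MTT | 6 s | pulmonary transit scale |
| PBF texture amplitude | 0.25 (×u, u clipped ±2) | ±50% regional heterogeneity |
| T1 texture amplitude | 0.05 | mild regional T1 variation |
| defect PBF scale | 0.2 | 80% flow reduction (5× contrast) |
| defect T1 scale | 0.85 | 15% shortening of the observed T1 |

The defect alteration scales *both* compartment T1s by one factor, which
scales the observed T1(TE) by exactly that factor at every echo time.
This keeps the designed shortening interpretable (ΔT1 ≈ 15% regardless of
TE) and separates the relaxation change from the perfusion deficit, which
is a separate PBF scale. A consequence is that the phantom's T1 and PBF
fields share one texture field, so local T1–PBF correlations are positive
by construction — the structure the local statistics are designed to
detect.

Observed T1 is the weight-averaged compartment T1 (an exact
mono-exponential target for the fitter) rather than a bi-exponential
recovery; the TE dependence enters through the T2\*-dependent weights.
Noise is Gaussian, not Rician; at the signal-to-noise levels simulated
the difference is second order, but magnitude-background statistics are
not faithfully Rician — a known limitation.

### Acquisition defaults

Echo times follow the five-echo UTE protocol (70, 500, 1200, 1650,
2300 μs). The inversion-time grid models a sliding-window reconstruction
of golden-angle spokes sorted by TI across all inversion blocks: with
300 spokes per 1.5 s block at TR 5 ms, 50% respiratory gating, and a
120-spoke window stepped by 60 spokes, windows average 60 ms of TI and
step 30 ms, giving TI = 30…1470 ms in 49 frames. This grid is a
reconstruction-derived stand-in (the true TI grid of such acquisitions is
implementation-specific) and is fully configurable. It matters
quantitatively: a 4-point TI grid makes the 3-parameter magnitude fit
information-poor (Cramér–Rao bound above 13% relative SD at SNR 20),
whereas the 49-frame grid supports recovery at a few percent.

DCE uses 20 frames at 1.7 s, gamma-variate AIF (shape 3, scale 1.5 s,
onset at frame 3, peak amplitude 4 in relative-enhancement units), and an
arterial blob carrying the AIF directly — about 10× the peak tissue
enhancement, which is what the automatic AIF detector exploits.

SNR is defined against the mean lung equilibrium signal at TE1 (IR
series) and the lung baseline signal (DCE); "SNR 20" sets σ to 1/20 of
those references.

## T1 fitting

The magnitude model S(TI) = |A − B e^(−TI/T1\*)| is fit per voxel by
variable projection: for fixed T1\* the model is linear in (A, B) once the
magnitude sign pattern is fixed, and with ascending TIs the sign flips at
most once, near the signal minimum. The fitter searches flip positions
within ±5 samples of the per-voxel minimum (plus the no-flip ends),
solves the 2×2 normal equations in closed form, scans a coarse log-spaced
T1\* grid, and refines by golden section — all vectorized across voxels.
This solves the same least-squares problem as a per-voxel trust-region
optimizer but with no initialization sensitivity and orders of magnitude
faster at 10⁴–10⁵ voxels. Noiseless recovery is exact to ≪0.1%.

Look-Locker correction T1 = T1\*·(B/A − 1) converts the apparent to the
true T1; the phantom's default inversion efficiency B/A = 2 makes the two
equal. Fits are declared invalid when inputs are non-finite, A ≤ 0,
B ≤ A, the signal is flat, or T1 falls outside the 100–3000 ms
plausibility window (values are clamped and flagged); invalid voxels are
excluded from every downstream median and correlation.

## Perfusion chain

Signal is converted to relative enhancement C = (S − S0)/S0 over the
first 3 (pre-onset) frames, assuming linearity — appropriate for a
low-dose protocol; no T1-based conversion is attempted. AIF detection
takes enhancing voxels (peak > 0.2), keeps the top percentile (99th) by
peak with time-to-peak at or below the median, and averages the top 20
curves. Deconvolution builds the lower-triangular Toeplitz matrix from
Δt·AIF, decomposes it once, and zeroes singular values below 0.15·σ_max.
The truncation biases the residue peak low by ~5% on the default phantom
(the accepted bias/noise trade of truncated SVD); λ is exposed in the
configuration. Delay-insensitive (block-circulant) deconvolution is not
implemented; the phantom has no AIF delay dispersion — a limitation for
real data.

t_max maximizes the lung-mean residue over frames (ties to the earliest
frame; with an onset-aligned AIF this is lag 0 by construction). The
two-threshold Otsu search is exhaustive over all bin pairs of a 256-bin
histogram, with a 1e−9 relative tolerance and lexicographic tie-break on
the maximizer so that near-degenerate histograms resolve identically
regardless of summation order. Classification, QDP, t_max and thresholds
are computed on the full 3D segmented lungs; QDP for comparison with the
2D T1 slices is then re-evaluated on slab projections (the three DCE
slices nearest each UTE slice; continuous maps averaged, label maps by
majority vote with defect winning ties — conservative toward defect
detection).

PBF is reported raw in s⁻¹ and calibrated to mL/100 mL/min by a single
configurable factor (6000 by default); all correlation statistics are
rank-based and therefore calibration-invariant.

## Correspondence

"Vertical" is the image row axis (head–foot on coronal slices). Each lung
is subdivided by ranking voxels on the row coordinate (ties by column,
then raster order) into 10 equal-count strips, and each strip by the
column coordinate into 10 equal-count blocks. The rank rule makes the
partition deterministic and enumeration-order invariant; equal "volume"
is equal voxel count per 2D slice. The same 10×10 scheme is applied per
lung regardless of lung size, which assumes comparable lung volumes.
Deformation fields (displacements in source-grid voxels) are applied by
pull-back resampling — bilinear for continuous maps, nearest-neighbour
for labels (never inventing labels; out-of-domain samples are flagged).
Registration itself is out of scope: fields are inputs, identity by
default, and an identity field between different grids is exactly
cross-grid resampling.

Region-growing segmentation admits, sweep by sweep, all face-neighbours
within a tolerance of the running region mean, then fills holes. A region
reaching the image border or exceeding half the image aborts — the seed
leaked out of the target structure. Seeds and tolerance are
configuration-driven.

## Statistics

Spearman's ρ is the Pearson correlation of average ranks, with pairwise
deletion of non-finite pairs; p-values use the t approximation, or exact
permutation enumeration for n ≤ 9. The Wilcoxon rank-sum test enumerates
the exact rank-sum distribution when both groups have ≤ 8 observations
(ties included) and otherwise uses the tie-corrected normal
approximation. ΔT1 uses the normal-class median as denominator, making it
the fractional shortening of defect tissue. No multiple-testing
correction is applied across echo times; significance is p < 0.05 on raw
p-values. Cohort-level local correlations are reported as mean ± SD with
n over subjects with evaluable values.

## Coupled cohort

`run_cohort` draws one latent severity s ~ U(0,1) per subject and sets
defect fraction 0.05 + 0.50·s, baseline tissue T1
1250 − 250·s + N(0, 50) ms, and normal-region PBF
0.05·(1 − 0.5·s)·lognormal(0, 0.15) s⁻¹. A fraction 4/22 of subjects get
a single UTE slice (the rest two, pooled voxel-wise before medians). This
coupling yields the qualitative structure the statistics target: across
subjects, median T1 rises with median PBF and falls with QDP; within
subjects, defect voxels have lower flow and shorter T1.

One deliberate non-goal: the cohort does *not* emulate the mechanism
where uniformly damaged lungs have too little perfusion spread to
correlate (which would make weak local correlations coincide with short
T1). In this generator, more-severe subjects are more bimodal and
correlate more strongly, so the correlation of local coefficients with
median T1 comes out negative rather than positive. The mechanism itself
is demonstrated by a dedicated simulation in the statistics tests.

## Problem sizes and determinism

Default desk-scale grids are 64×64 for the UTE slice and 16×52×64 for the
DCE volume (the paper-scale 128×128 / 208×256×56 geometries are pure
configuration changes); a 22-subject cohort completes in about three
minutes on one CPU. Every random draw derives from a single integer seed
(subject seeds are fixed arithmetic functions of it, kept below 2³¹), and
identical configuration plus seed reproduces bit-identical outputs;
outputs embed the configuration hash and seed.

## What the phantom validation shows — and does not

Passing tests establish that the implementation inverts its own forward
models correctly (T1 fitting, deconvolution, classification), that the
algorithmic components match independent oracles (Otsu, rank statistics,
subdivision), and that the statistical machinery detects the coupled
structure it is pointed at. They do not establish accuracy on real lung
MRI: the phantom has no respiratory motion or registration error, no
contrast-nonlinearity or T2\* signal loss, no AIF delay/dispersion,
Gaussian rather than Rician noise, ellipse-based anatomy, and a
mono-exponential recovery target. Quantities tied to those effects (e.g.
absolute PBF calibration, behaviour under failed registration) are out of
scope of what these simulations can certify.
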