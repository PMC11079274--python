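# Methods

## Model

Transient lung hypoxia under isocapnia raises arterial deoxyhemoglobin
(dOHb), an intravascular paramagnetic tracer. For a voxel with relative
blood volume rCBV and mean transit time MTT, indicator-dilution theory with
a mono-exponential residue function R(t) = exp(−t/MTT) gives the tissue
tracer content as rCBV·(Ca ⊛ R)(t), with Ca(t) the arterial concentration.
The analysis works in the *signal domain*: concentration is identified with
the relative signal drop c(t) = (S₀ − S(t))/S₀ rather than with
ΔR2* = −ln(S/S₀)/TE. For drops of a few percent the two differ by <3%
(Taylor expansion of −ln(1−x)), and the signal-domain choice makes the
linear forward model exact; the log-domain conversion is retained behind
`domain="log"` for sensitivity analyses.

Discretization: the residue kernel h(t) = exp(−t/MTT)/MTT is sampled at
t_k = k·TR and renormalized so Σh·TR = 1 over the series; the convolution
is causal with left-Riemann weighting. The identical code path
(`dohbperf.kinetics`) serves the phantom's forward simulator and the
inverse fit, so discretization error cancels in recovery tests. Kernel
truncation is negligible because the series (~288 s) is far longer than
the largest admissible MTT (8 s).

Fit: for fixed MTT the optimal rCBV is the closed-form projection
⟨c, m⟩/⟨m, m⟩, clipped at zero (no negative blood volume). MTT is found by
a dense grid search over [1, 8] s at 0.01 s followed by a bounded local
refinement (scipy `minimize_scalar`, tolerance 10⁻⁶ s) within one grid
cell; ties resolve to the smaller MTT, making the estimator deterministic
and checkable against an exhaustive brute-force enumeration (the oracle in
`tests/oracles.py`). MTT estimates at the bounds are counted as "clamped"
and reported, not altered. rCBF = rCBV/MTT × 30 a.u. voxelwise; all outputs
are relative, and no AIF partial-volume, delay, dispersion, or leakage
correction is applied (the tracer is assumed to remain intravascular, and
the model carries no delay parameter).

## Stimulus and regressor

The programmed waveform is piecewise constant: 60 s baseline at 95 mmHg,
60 s at 40 mmHg, a normoxic interlude, a second 60 s hypoxic step, and a
recovery — 260 s total with the default 30 s interlude and 50 s recovery
(midpoints of the allowed 20–40 s and 40–60 s ranges). Transitions are
modeled as instantaneous steps; no lung washout kinetics and no end-tidal
measurement noise. Samples on a segment boundary belong to the later
segment (causal acquisition). End-tidal O₂ converts to saturation by a
Hill curve, saO₂ = pO₂ⁿ/(pO₂ⁿ + p50ⁿ), with textbook adult defaults
p50 = 26.8 mmHg and n = 2.7 (both configurable); the regressor is the
baseline-saturation excess dOHb(t) = saO₂(0) − saO₂(t), clipped at zero
(≈0.221 at the hypoxic plateau). End-tidal CO₂ is metadata only —
isocapnia is a hardware guarantee of the gas blender. The scan (160
volumes × 1.8 s ≈ 288 s) outlasts the stimulus; traces are extended by
holding the final, normoxic target.

QC regresses each voxel's time course on (intercept, dOHb) by OLS and
summarizes R² over a tissue mask; a subject fails when the median R² falls
below a configurable threshold (default 0.1 — the original exclusion was
made without a printed cutoff). Regressing on end-tidal O₂ directly is
possible by passing that trace instead.

## Phantom

A labeled ellipsoidal head (GM shell, WM core, central CSF) with a nested
lesion — necrotic core inside a contrast-enhancing shell inside an edema
halo — strictly confined to one hemisphere so that mid-plane flipped masks
sample healthy tissue, plus a small artery block near the skull base.
Default grid 24×24×12 at 2.5 mm isotropic, TR 1.8 s, TE 30 ms, 160 volumes:
a desk-scale volume that keeps the full suite in seconds while preserving
all structural features (the geometry scales with the grid).

Compartment defaults (rCBV a.u., MTT s, S₀ a.u.): GM (0.29, 3.5, 800),
WM (0.24, 3.9, 850), CSF (0.02, 2.0, 500), CE (0.53, 4.0, 750), necrosis
(0.05, 6.0, 700), edema (0.36, 3.7, 780). MTTs and rCBV *ratios* follow
the cohort GM/WM/CE/edema means; the absolute rCBV scale is set so that
with the default arterial amplitude k_a = 0.15 the tissue signal drops
stay in the few-percent range typical of dOHb-contrast BOLD. Since all
outputs are relative, this global scale is a free choice. Artery voxels
carry the input itself, S = S₀·(1 − Ca). Noise is additive Gaussian,
independent per voxel and time point, default sd 8 (GM tSNR = 100); no
drift, motion, or EPI artifacts are simulated, because the preprocessing
that removes them is outside this package's scope. Passing recovery tests
on this phantom therefore demonstrates correctness of the deconvolution
under its own model assumptions — not robustness to motion, delay or
dispersion in real scanner data.

## Smoothing

"Adaptive mean filtering of width 7 mm" is implemented as a
mask-restricted cube-kernel mean: kernel side ceil(7/2.5) rounded up to
odd (3 voxels), divisor equal to the count of in-mask neighbors, so brain-
edge voxels average only over valid tissue. The filter is optional in
`fit_maps` (`filter_width_mm=None`): noiseless recovery runs disable it
because averaging across compartment boundaries mixes curves with
different MTTs, which is a property of any spatial smoothing rather than
of the estimator; the noisy pipeline keeps it, which is what makes
voxelwise rCBV errors of a few percent achievable at tSNR 100.

## ROI statistics

Raw CE/necrosis/edema masks are composed with precedence necrosis > CE >
edema (radiological nesting; overlap resolution is otherwise unspecified
in practice), tumor = CE ∪ necrosis, whole lesion = tumor ∪ edema, and GM/
WM have the whole lesion removed. Flipped counterparts mirror each lesion
ROI about the grid mid-plane (index i → n−1−i), which assumes roughly
midline-centered volumes; nonlinear symmetric-template flipping is out of
scope. ROI values are unweighted means; an absent compartment yields a
missing value, not an error. Cohort rows report the arithmetic mean,
**population** standard deviation (÷n — recomputing the reference tables
shows the printed SDs match the population formula, e.g. age 13.8, GM MTT
1.1), min and max; rounding happens only at presentation.

The bundled reference table (`dohbperf.datasets`) reproduces the published
GM/WM aggregate rows exactly from its per-patient rows. The printed
CE/edema aggregate means do *not* recompute from the printed per-patient
values; only the GM/WM columns are used as anchors and the discrepancy is
left as a property of the source tables.

## Problem sizes and numerical choices

The test suite and the acceptance script use the 24×24×12×160 phantom
(~2800 fitted voxels) and 16×16×8×80 variants for unit tests; both
complete in seconds and exercise every code path at full temporal
resolution. The MTT grid step is 0.01 s (refined to 10⁻⁶ s); the brute-
force oracle uses a 0.05 s MTT grid with a two-stage rCBV enumeration
(0.02 then 2×10⁻⁴). Degenerate inputs are handled explicitly: all-zero
tissue curves fit (rCBV 0, MTT at the lower bound, rss 0); an all-zero AIF
raises a fit failure; voxels with non-positive baseline are excluded from
the fit mask and counted.

## Known limitations

- No slice-time/motion correction, registration, or segmentation — inputs
  are assumed preprocessed and co-registered.
- No AIF delay/dispersion modeling and no nonparametric (SVD/Tikhonov)
  deconvolution; the estimator is exactly the parametric mono-exponential
  model.
- Absolute quantification is impossible by construction; rCBV/rCBF are
  arbitrary-unit quantities tied to the (unnormalized) AIF amplitude.
- The phantom's noise model (white Gaussian) understates physiological
  structure in real BOLD residuals.
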