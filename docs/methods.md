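# Methods

## Optical model

Excitation light of vacuum wavelength λ₀ arrives through the coverslip
(refractive index n₃) at the interface with the aqueous sample (n₁) at an
incidence angle θ above the critical angle θc = arcsin(n₁/n₃). The
evanescent intensity decays as I(h) = e^(−τh) with distance h from the
coverslip, with penetration depth

d = λ₀ / (4π n₃) · (sin²θ − sin²θc)^(−1/2),  τ = 1/d.

For the canonical configuration (λ₀ = 447 nm, n₁ = 1.33, n₃ = 1.53,
θ = 63°) the computed critical angle is 60.38° and d ≈ 118.9 nm
(τ ≈ 0.0084 nm⁻¹). Published descriptions of this configuration sometimes
quote θc = 60.8° — consistent with a slightly higher solution index — which
gives d ≈ 130.2 nm. Rather than silently preferring one reading,
`OpticalConfig` computes θc from the indices by default and accepts an
explicit `critical_angle_override`; both readings round to
τ = 0.008 nm⁻¹, the value used for the canonical layer grid. Polarization,
intermediate refractive layers and fluorophore orientation are outside the
model.

The continuous decay is discretized over N molecular layers of thickness
Δh (default 50 layers × 10 nm, roughly the size of a PH-domain probe fused
to a fluorescent protein). Layer i is illuminated at its coverslip-proximal
edge, Iᵢ = e^(−τ·i·Δh), so the membrane layer (i = 0) has I₀ = 1. With
τ = 0.008 nm⁻¹ the 50-layer truncation discards e^(−4) ≈ 1.8% of the
infinite-series illumination; a warning is raised whenever a user-chosen
grid discards more than 5%. On this grid the membrane layer carries
I₀/ΣI ≈ 7.8% of the total illumination. A figure of ~5% is sometimes
quoted for this geometry; the package always reports the computed
fraction — 7.8% for the stated grid — rather than reproducing the quoted
one, and the discrepancy is logged where the fraction is derived.

## Translocation model

At rest the probe is assumed homogeneously distributed: m molecules in
each layer, no membrane binding. Baseline fluorescence is
F_initial = B·Σᵢ m·Iᵢ; normalizing traces to baseline sets F_initial = 1,
which fixes m = 1/(B·ΣIᵢ) ≈ 0.0783 (≈ 0.08) for the canonical grid and
removes the per-molecule brightness B from every subsequent ratio.

Stimulation moves Δm molecules to the membrane layer. Two scenarios
bracket the source of those molecules:

- **fixed_total** — the field holds a fixed pool; recruitment drains all
  N layers evenly: F = Δm·I₀ + Σᵢ (m − Δm/N)·Iᵢ. Valid for
  1 ≤ F ≤ N·m·I₀ (≈ 3.92 on the canonical grid; larger F would imply
  negative cytosolic density).
- **fixed_cytosol** — cytosolic layers stay at m; molecules are added to
  the membrane layer from an unmodeled reservoir:
  F = (m + Δm)·I₀ + Σ_{i≥1} m·Iᵢ.

Both equations are affine in Δm, so the inversion is closed-form; a
numeric root-find of the same equations is kept in the test suite as an
independent oracle (agreement to 1e−10, and forward/inverse round trips to
1e−10 across the admissible range). The headline output is the membrane
ratio R_m = (m + Δm)/m. For F = 1.54, R_m ≈ 10.3 (fixed_total) or ≈ 7.9
(fixed_cytosol); the two assumptions agree within 25%, so the conclusion
— an order-of-magnitude membrane increase behind a 1.5-fold total-signal
change — is robust to the choice.

Fold-changes below 1 (net probe loss, e.g. under PI3K inhibition) are
outside the redistribution model and rejected by default;
`allow_depletion=True` extrapolates the affine equations to Δm < 0 with a
warning, which the cohort machinery uses to summarize inhibitor-like
conditions. The model is static: binding kinetics, diffusion,
photobleaching and phosphatase dynamics are not represented.

## Trace pipeline

Per frame, the footprint ROI mean and a background ROI mean are taken; the
background trace is subtracted elementwise (values ≤ 0 are kept, not
clipped — clipping would bias normalization — and trigger a warning); the
corrected trace is divided by its mean over the pre-treatment baseline
window [−T_b, 0). T_b defaults to 60 s but is a parameter (120 s is an
equally common convention and is what the synthetic experiments record).
Treatment-window summaries are means over half-open windows [start, end)
in minutes on frame timestamps, so boundary frames are assigned
deterministically. Four named presets cover the usual reporting choices:
`akt_ph_early` (4–6 min), `akt_ph_late` (6–8 min), `channel_early`
(8–10 min), `channel_late` (10–12 min); none is claimed to be canonical.
The normalized trace is invariant to camera gain and to any offset shared
by the two ROIs, and normalization is idempotent — all three are tested
properties. ROIs are inputs (binary masks or polygon CSVs rasterized with
scikit-image); footprint segmentation, drift and bleach correction are out
of scope.

## Cohort statistics

Window summaries are pooled per condition (cells across experiments;
batch is not modeled). Because response distributions are right-skewed,
condition pairs are compared with the two-sided Wilcoxon–Mann–Whitney
rank-sum test: exact enumeration when min(n_a, n_b) ≤ 12 and the pooled
data are tie-free, otherwise the normal approximation with tie and
continuity corrections (the 12 cutoff keeps exact enumeration cheap while
the approximation is already accurate there; exact and asymptotic p agree
within 0.01 at n ≥ 15 in the tests, and the null rejection rate at
α = 0.05 calibrates to 0.05 ± 0.01 over 10⁴ simulated nulls). Families of
pairwise comparisons reported together are Holm–Bonferroni adjusted;
family membership is an explicit argument, never inferred. Paired designs
use the paired Student t-test. Blot densitometry is normalized per blot
by the blot mean (removing exposure/gain) and per lane by the
blot-mean-normalized pan-antibody reference. Summaries are mean ± SEM
(sample SD/√n). Effect sizes, confidence intervals and mixed models are
deliberately out of scope.

## Synthetic-data generator

The generator is the package's ground truth. Per cell, recruitment
follows Δm(t) = A·(1 − e^(−(t−t₀)/τ_r))·(p + (1−p)·e^(−(t−t₀)/τ_d)) for
t > t₀ — a delayed rise with optional partial relaxation. This is a
generator choice, the simplest shape matching the observed phenomenology
(biosensor responses rise within minutes and partially relax under
sustained stimulation; channel trafficking plateaus, p = 1); it is not a
mechanistic claim. Defaults: delay 30 s, rise 60 s; the responder template
uses p = 0.7 with τ_d = 300 s.

Cohort templates (defaults fixed once, from the published cohort-level
statistics of this experimental system):

- **responder** (n = 100): amplitudes log-normal with median 0.56 and
  log-scale σ = 1.0 — right-skewed, giving a cohort-mean window
  fold-change ≈ 1.5 with positive skew. Amplitudes are truncated at 95%
  of the fixed-total pool capacity N·m, since a cell cannot recruit more
  molecules than the field holds.
- **vehicle** (n = 20): amplitude 0; summaries scatter around 1.
- **inhibitor** (n = 60): sign-flipped response with amplitude ≈ 0.16
  (σ = 0.1), putting the window mean near 0.88.

Ground-truth F(t) comes from the forward translocation model; the
per-cell true R_m is the inversion of the true window-mean F under the
experiment's scenario.

Two measurement routes exist. The **rendered** route draws camera frames:
an elliptical footprint (~1000 px in a 96 × 96 frame) at
background + baseline·F(t) photons per pixel, Poisson photon noise,
Gaussian read noise (σ = 3) and a constant camera offset, with defaults of
150 baseline and 30 background photons per pixel — per-pixel CV ≈ 9%, a
realistic camera regime, which makes the ~1000-pixel ROI mean precise to
a few tenths of a percent per frame. The **trace-level fast path** skips
rendering and applies 1.5% per-frame multiplicative noise directly to
F(t); it is deliberately noisier per frame because it stands in for
everything the pixel model omits (baseline drift, focus fluctuations,
cell movement), and it is flagged in the output. Both routes then use the
real pipeline operations (baseline normalization, window summary). An
earlier design targeted ~1% ROI-mean CV for the rendered route as well;
that was revised because the Δm inversion amplifies F-measurement error
by 1/(m·(I₀ − ΣI/N)) ≈ 17 on the canonical grid, which at 1% ROI-mean CV
makes R_m recovery unreliable for weakly responding cells — an artifact
of unrealistically dim rendering, not of the estimator. With the default
rendering noise, pipeline-recovered window fold-changes and inverted R_m
are within 5% (relative) of ground truth for ≥ 95% of rendered responder
cells (tested at n = 60 cells, fixed seed).

All randomness derives from explicit integer seeds; identical spec + seed
produces bit-identical stacks. The generator does not emulate subcellular
structure, vesicle dynamics, probe-binding kinetics, bleaching or stage
drift — passing tests certify the quantification chain (extraction,
normalization, inversion, statistics), not robustness to those real-data
features.

## Problem sizes and determinism

Default simulated experiments run 73 frames at 10-s intervals (2 min
baseline + 10 min treatment). Test-suite simulations use cohorts of tens
of cells and a 60-cell rendered recovery study; the type-I-error
calibration uses 10⁴ null replicates at n = 20 per group. These sizes
were chosen to characterize the estimators well while keeping the full
suite fast to iterate on. Degenerate inputs (empty masks, sub-critical
incidence, zero baselines, zero-variance differences, fold-changes
outside a scenario's range) raise `ValueError` with specific messages
rather than propagating NaNs.
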