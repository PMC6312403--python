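# tirfquant

Quantification of membrane translocation from TIRF microscopy time series.

In total internal reflection fluorescence (TIRF) microscopy the evanescent
excitation field decays exponentially with distance from the coverslip, so
the recorded footprint signal of a soluble fluorescent biosensor — for
example a PH-domain lipid probe that moves from cytosol to plasma membrane
when PI3K is activated — mixes a small membrane-proximal contribution with
a large cytosolic one. A modest change in *total* footprint fluorescence
can therefore correspond to a very large change in the *membrane-bound*
probe. `tirfquant` implements the full chain needed to make that
correction quantitative:

- **optics** — critical angle θc = arcsin(n₁/n₃), penetration depth
  d = λ₀/(4πn₃)·(sin²θ − sin²θc)^(−1/2), decay constant τ = 1/d, and the
  discretized illumination profile Iᵢ = e^(−τ·h) over 10-nm molecular
  layers;
- **translocation** — the layered redistribution model: with the baseline
  normalized to F_initial = B·Σᵢ m·Iᵢ = 1, a measured fold-change F is
  inverted in closed form for the number of recruited molecules Δm and the
  membrane ratio R_m = (m + Δm)/m, under either a fixed-total pool
  (recruitment drains all layers evenly) or a fixed-cytosol scenario
  (molecules added to the membrane layer only);
- **traces** — ROI mean-intensity extraction from image stacks, background
  subtraction, baseline normalization, treatment-window summaries;
- **stats** — cohort mean ± SEM, two-sided Wilcoxon–Mann–Whitney rank-sum
  tests (exact for small tie-free samples), Holm–Bonferroni step-down
  adjustment, paired t-tests, and immunoblot densitometry normalization;
- **simulate** — a ground-truthed synthetic generator (kinetics → forward
  optics model → noisy rendered camera frames) so the whole chain is
  testable end to end without any external data.

It is intended for experimentalists analysing two-channel TIRF time-lapse
recordings of biosensor translocation and channel trafficking, and for
anyone who wants to reason about how badly cytosolic contamination
understates membrane recruitment.

## Worked example

A typical objective-type TIRF configuration: 447 nm excitation through
glass (n₃ = 1.53) into saline (n₁ = 1.33) at 63° incidence, and a measured
biosensor fold-change of 1.54 after growth-factor stimulation.

```python
from tirfquant import (OpticalConfig, penetration_depth, illumination_profile,
                       solve_resting_density, estimate_translocation)

config = OpticalConfig(wavelength=447, n_solution=1.33, n_coverslip=1.53,
                       incidence_angle=63)
field = penetration_depth(config)
print(f"critical angle : {field.critical_angle:.2f} deg")
print(f"depth d        : {field.depth:.1f} nm")
print(f"decay tau      : {field.decay:.4f} /nm")

grid = illumination_profile(0.008)          # 50 layers x 10 nm
resting = solve_resting_density(grid)
print(f"membrane fraction I0/SumI : {grid.membrane_fraction:.3f}")
print(f"resting density m         : {resting.molecules_per_layer:.4f}")

for scenario in ("fixed_total", "fixed_cytosol"):
    est = estimate_translocation(1.54, resting, scenario)
    print(f"{scenario:14s}: delta_m = {est.delta_m:.3f}, R_m = {est.membrane_ratio:.2f}")
```

prints

```
critical angle : 60.38 deg
depth d        : 118.9 nm
decay tau      : 0.0084 /nm
membrane fraction I0/SumI : 0.078
resting density m         : 0.0783
fixed_total   : delta_m = 0.725, R_m = 10.26
fixed_cytosol : delta_m = 0.540, R_m = 7.89
```

Reading: the evanescent field penetrates ~119 nm, so only ~7.8% of the
resting signal comes from the 10-nm membrane layer — the rest is cytosolic
contamination. Inverting the 1.54-fold total-signal increase shows it
actually represents roughly **ten times** more membrane-bound probe
(R_m ≈ 10 with fixed-total redistribution, ≈ 8 if cytosolic layers are held
constant — the two bracketing assumptions agree within 25%).

The same chain is available from the shell:

```bash
tirfquant optics --incidence-angle-deg 63
tirfquant estimate -f 1.54 --scenario fixed_total
tirfquant extract --stack stack.tif --cell-mask cell.png --background-mask bg.png
tirfquant simulate --spec experiment.yaml --outdir simulated/
```

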