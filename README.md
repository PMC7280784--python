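# mtrepair

Quantitative analysis of microtubule mechanics and lattice repair from
single-filament fluorescence microscopy: persistence-length inference from
flow-bent filament shapes, intensity quantification at laser-damage sites,
erfc-based plus-end tip localization, and rule-based classification of
damage and repair events. All stages run end-to-end on seeded synthetic
data with known ground truth, so the full pipeline is testable without any
microscope recordings.

The package is aimed at in-vitro reconstitution labs that bend dynamic
microtubules with hydrodynamic flow in microfluidic chambers, damage them
with pulsed lasers, and read out repair from dual-channel TIRF intensities.

## The model

A microtubule is an inextensible slender elastic rod of length *L* and
bending rigidity *κ* (pN·µm²), clamped at the GMPCPP seed (fixed position
and tangent at *s* = 0) and free at *s* = *L*. Its elastic energy is

    E[r] = ∫₀ᴸ [ (κ/2) (d²r/ds²)² + (λ/2) ((dr/ds)² − 1) ] ds,

with λ(s) the Lagrange multiplier enforcing |dr/ds| = 1. The fluid exerts
an anisotropic slender-body drag per unit length

    f_H = g μ (I − ½ t⊗t) v(r),

where **t** is the unit tangent, **v** the flow velocity (µm/s, e.g. from
bead tracking), μ the viscosity (10⁻³ pN·s/µm² for water) and *g* a
geometric factor of order one. Perpendicular drag is exactly twice the
parallel drag. Equilibrium shapes solve the force/moment balance
F_B + F_H = 0; `mtrepair` solves this boundary-value problem in a
tangent-angle parameterization (which makes inextensibility exact) with
continuation in flow magnitude.

The rigidity of a measured filament is the minimizer of the shape distance

    ω²(κ) = (1/L) ∫₀ᴸ |r_R(s) − r(s; κ)|² ds,

between the measured curve r_R and the model curve r at the same flow,
optionally together with a small rigid origin offset absorbing seed
digitization error. The persistence length is L_p = κ / (k_B T). Per-cycle
L_p values from repeated bending are normalized to the first cycle, and
softening is a significant negative Spearman rank correlation of L_p with
cycle number (exact permutation p-value for ≤ 8 cycles).

The intensity side implements the standard damage-site normalizations
(mean pre-damage intensity → 1; intensity immediately after damage → 1),
min–max percent normalization, plus-end localization by fitting
I(x) = ½ I_MT erfc((x − x_PF)/(√2 σ)) + I_BG, tip-aligned profile
averaging, and OLS slope fitting of the initial linear incorporation
phase. Event classification covers damage outcomes I/II/III (bending >10°,
intensity reduction, severing), breakage vs straightening, severed-end
fates (regrowth / depolymerization to seed / rescue), and detection of
≥1 µm lattice gaps with complete vs partial green-tubulin fill-in.

## Worked example

```python
import numpy as np
from mtrepair import (MechanicalParams, UniformFlow, equilibrium_shape,
                      fit_kappa, BendingSeries, normalize_series,
                      softening_test)
from mtrepair.mechanics import FilamentShape

# forward model: kappa = 50 pN um^2 filament in a 100 um/s orthogonal flow
params = MechanicalParams(kappa=50.0, mu=1e-3, g=1.0, temperature=308.15)
flow = UniformFlow(0.0, 100.0)
sol = equilibrium_shape(params, length=10.0, flow=flow, n_nodes=61)
print(f"tip deflection: {sol.shape.points[-1, 1]:.3f} um")

# add one pixel of digitization noise, resample, and fit kappa back
rng = np.random.default_rng(0)
noisy = sol.shape.points + rng.normal(0.0, 0.063, sol.shape.points.shape)
measured = FilamentShape.from_points_resampled(noisy, n_points=61,
                                               smoothing=2 * 61 * 0.063**2)
fit = fit_kappa(measured, flow, params, fit_origin=True)
print(f"kappa_hat = {fit.kappa_hat:.1f} pN um^2, Lp = {fit.lp/1000:.0f} mm, "
      f"omega^2 = {fit.omega2_min:.2e} um^2")

series = BendingSeries("mt000", [[1.00], [0.93], [0.85], [0.78], [0.70], [0.66]])
series = softening_test(normalize_series(series), alpha=0.05)
print(f"rho = {series.spearman_rho:.2f}, p = {series.p_value:.4f}, "
      f"softened = {series.softened}")
```

prints

```
tip deflection: 2.368 um
kappa_hat = 51.8 pN um^2, Lp = 12 mm, omega^2 = 1.50e-04 um^2
rho = -1.00, p = 0.0014, softened = True
```

The filament deflects 2.37 µm under the flow; the fit recovers the true
rigidity (50 pN·µm²) to 3.6% despite one pixel of coordinate noise, and a
strictly decreasing six-cycle L_p series is flagged as softening with the
exact one-sided permutation p-value 1/720.

A `mtrepair` console command exposes every stage
(`generate`, `fit-lp`, `softening-test`, `fit-tip`, `damage-normalize`,
`incorporation-rate`, `classify-damage`, `detect-incorporation`, `run`);
the full synthetic pipeline runs with

```sh
mtrepair run --config examples/demo_config.yaml --out demo_run
```

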