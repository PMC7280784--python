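# Methods

## Mechanical model and solver

The filament is a planar inextensible Euler elastica: position r(s) with
|dr/ds| = 1, bending rigidity κ, clamped position and tangent at the seed
(s = 0), force- and moment-free at the distal end (s = L). The distributed
load is anisotropic slender-body drag, f = g·μ·(I − ½ t⊗t)·v(r), so a
straight filament feels exactly twice the drag perpendicular to its axis
as parallel to it. Bending is treated as quasi-static: each measured
snapshot is assumed to be an equilibrium shape of the instantaneous flow,
which is appropriate because elastic relaxation of a ~10 µm microtubule is
fast compared with the 10 s flow-on periods of a bending cycle. Thermal
shape fluctuations, 3D bending, twist and time-dependent relaxation are
out of scope.

Rather than integrating the Euler–Lagrange equations with λ(s) as an
explicit unknown, the solver works in the tangent angle θ(s), which
enforces inextensibility identically. With the internal force
N(s) = ∫ₛᴸ f ds′ (zero at the free end by construction), moment balance
reads κ θ″(s) = −(t × N)_z with θ(0) fixed and θ′(L) = 0. The reported
`internal_tension` is the tangential component t·N, the physical content
of the inextensibility multiplier.

Discretization: second-order central differences for θ″ on a uniform grid
(default 61 nodes for a 10 µm filament), a second-order one-sided
difference for the moment-free end condition, reverse cumulative
trapezoid for N, and node positions laid down along mid-segment angles so
every chord has length exactly Δs. Residuals are scaled to angle units
(×Δs²/κ), and the root is found with MINPACK's hybrid Newton method to a
dimensionless tolerance of 1e-10. The flow magnitude is ramped from zero
in 10 continuation steps, which keeps the solver on the physically
connected branch of the multi-branched high-load elastica; warm starts
from a neighbouring solution skip continuation when they already converge.
Doubling the node count moves the tip by <0.5% in the regimes exercised
by the tests; the equilibrium shape depends on κ and g·μ only through the
ratio κ/(g·μ), which is verified as an invariance test.

Units are pN/µm/s with k_B = 1.380649×10⁻⁵ pN·µm/K, avoiding the float
underflow of SI values. g defaults to 1.0 and is a configuration
parameter; absolute κ (and hence absolute L_p) carries the g-scale
uncertainty, while per-cycle normalized values cancel it exactly (tested).
The default temperature is 308.15 K (the 35 °C stage temperature typical
of bending experiments); it enters only the κ → L_p conversion.

## Rigidity inference

ω²(κ) = (1/L)∫|r_R − r(κ)|² ds is evaluated by the trapezoid rule on the
common uniform arc-length grid. The outer minimization is bounded scalar
search on log₁₀κ over [−2, 6] (tolerance 1e-4 on log₁₀κ, i.e. ~0.02% in
κ); log spacing makes the bracket scale-free across the four decades of
plausible rigidities. The inner origin-offset optimization is exact: for
a rigid translation d the objective is mean w‖e − d‖² with trapezoid
weights w, minimized by the weighted mean residual vector, clipped
componentwise to ±2 pixels. The outer/inner order keeps the expensive
forward solves in a single 1D loop. Non-convergent forward solves during
the search return a large penalty; a fit is rejected only if every solve
fails. A fitted κ within 0.01 decades of a bracket edge sets a boundary
warning.

Measured (digitized) shapes must be resampled to a uniform arc-length grid
before fitting. Raw noisy polylines systematically inflate the apparent
contour length (E|Δr + η| > |Δr|), which would bias κ; resampling
therefore goes through a smoothing spline with budget ≈ 2·n·σ² for
coordinate noise of standard deviation σ per axis (the scipy `splprep`
convention), followed by uniform re-parameterization and per-segment
renormalization so the inextensibility invariant holds exactly. With the
default one-pixel noise (σ = 0.063 µm) this leaves a median κ error of
about 2–3% per shape (60-fit Monte-Carlo at κ ∈ {10, 50, 200} pN·µm²).

Per-cycle replicates (default five, any count ≥ 1 accepted) are averaged
arithmetically; normalized series divide each cycle mean by the cycle-1
mean. The softening test is a Spearman rank correlation of cycle-mean L_p
against cycle index, one-sided toward negative ρ by default (sidedness is
a flag). For ≤ 8 tie-free cycles the p-value is exact, from full
enumeration of the n! rank permutations (cached per n); beyond that, or
with ties, scipy's asymptotic approximation is used. A fully tied series
is degenerate: ρ undefined, verdict "not softened". Note the exact test
is discrete: with six cycles the attainable sizes are multiples of 1/720
with ties, and the largest attainable size ≤ 0.05 is 21/720 ≈ 0.029, so
the empirical type-I error of a correctly calibrated test sits at 0.029,
not at 0.05. Population comparison between conditions is a plain
two-sample t test on final-cycle normalized L_p; other summaries are
possible and the choice is deliberately minimal.

## Intensity analysis

Traces and profiles are background-subtracted arbitrary units. The
pre-damage normalization divides by the mean over a window before the
damage frame (default: the last five frames; a window in seconds can be
given instead), with an optional ×100 percent variant. The post-damage
normalization shifts time so the first frame at or after t_damage is
t = 0 and divides by that frame's intensity — "immediately after damage"
means the first acquired frame at or after the damage timestamp. Both are
invariant to detector gain. Min–max normalization maps a profile affinely
to [0, 100]%.

Tip localization fits ½ I_MT erfc((x − x_PF)/(√2 σ)) + I_BG by bounded
nonlinear least squares (trust-region reflective). Initial guesses come
from the 5th/95th intensity percentiles and the 10%/90% crossing
positions (their separation is 2.563 σ for an erfc edge); bounds keep
I_MT and σ positive and x_PF inside the scanned span. The profile is
assumed to run from the lattice plateau (small x) down to background; σ
collapsing to its lower bound flags a step-like degenerate fit. Aligned
averaging shifts each profile by −x_PF and linearly interpolates onto the
overlapping common grid. Incorporation rates are OLS slopes of
post-damage-normalized intensity on an explicit window [0, t_end]
(mirroring fixed analysis windows such as 45 s for tubulin alone and 20 s
with CLASP2α); automatic saturation detection is available as an optional
two-segment least-squares changepoint helper but is off by default.

## Event classification

All rules are deterministic and total on valid inputs. Bend angles are
measured between mean unit tangents of up to five segments on either side
of the site, invariant under rigid motions. Damage outcomes use
precedence III > I > II: severing (two new ends) beats bending
(angle > 10°, strict), which beats intensity reduction (drop fraction
> 0.1). Outcome-I fates: breakage if two ends ever appear; straightening
if the angle ever returns below threshold; otherwise unresolved. Severed
plus-end fates from the tip trajectory: depolymerization to seed if the
tip enters the seed interval; immediate regrowth if it never shrinks more
than 0.2 µm below the ablation site; rescue on the lattice if shrinkage
reverses to growth before the seed; the depolymerization length is the
site position minus the trajectory minimum.

Incorporation-site detection thresholds the red (original-lattice)
profile at 0.5× its median outside gaps, found by fixed-point iteration
from the global median. Gaps are kept if ≥ 1 µm long (intervals are
half-open [start, end) in µm; the frequency per µm counts gaps after this
filter) and green signal is present at both gap-edge samples; a site is
complete if green exceeds its threshold at every interior sample, partial
otherwise. The green threshold is background median + max(3× background
SD, 10% of the green dynamic range): the 3σ rule alone is undefined on
exactly noiseless synthetic profiles (SD = 0), and the dynamic-range
floor keeps the rule meaningful there; the comparison is strict. The 10°,
45° and 1 µm decision thresholds are printed experimental conventions;
the remaining numeric defaults (drop fraction 0.1, gap threshold 0.5,
regrowth tolerance 0.2 µm, flank of 5 nodes) were chosen once for clean
separability on synthetic data and are all configurable.

## Synthetic data

The generators are deterministic functions of (configuration, seed) and
each emits a machine-readable truth table, so every end-to-end test
compares pipeline output to generation truth. The bent-shape generator
emulates the bending-cycle protocol: 10 µm filaments, uniform orthogonal
flow of 100 µm/s (the regime where a κ = 50 pN·µm² filament deflects
~2.4 µm, comparable to observed bending), six cycles, five replicates per
cycle, a multiplicative per-cycle rigidity decline (default 10% per
cycle, the softening regime), ~10% log-normal scatter of first-cycle κ
across filaments, Gaussian coordinate noise of one 0.063 µm pixel per
axis, and a uniform ±1 px seed-origin offset per filament. Tip profiles
are erfc curves with I_MT ∈ [80, 120], I_BG ∈ [5, 15], σ ∈ [0.2, 0.4] µm
at 0.065 µm sampling and 5 a.u. noise. Damage traces are flat pre-damage,
an instantaneous drop at the damage frame and a linear rise to a plateau
(defaults give the 5.4-fold recovery regime); lattice pairs place red
intensity wells at specified gaps with green fill patterns full /
edges-only / interior-hole / none.

What the generators do not emulate: camera noise physics (shot noise,
EMCCD gain), photobleaching, drift, non-equilibrium filament dynamics
during flow switching, spatially non-uniform flow profiles near surfaces,
and correlated digitization errors from filament-tracing software.
Passing tests therefore demonstrate correctness of the estimators and
rules under the stated noise models, not robustness to every artifact of
real recordings; on real data the g-factor and flow-field uncertainty
dominate absolute L_p accuracy, which is why the per-cycle normalized
analysis is the primary readout.

## Problem sizes and numerical defaults

Default problem sizes were chosen as the smallest that leave the
estimators' error regimes clearly visible: 61 nodes per 10 µm filament
(41 in the quick pipeline demo), 10 continuation steps, 20 shapes per κ
in recovery studies, 200 repeats for tip-fit error estimates, and 1000
replicates for test-calibration rates. Monte-Carlo acceptance bounds
(median κ error ≤ 6% at one-pixel noise; tip-position RMSE ≤ 0.03 µm at
5 a.u. noise) were frozen from seeded oracle runs performed before the
acceptance suite was written, with headroom for seed-to-seed variation,
and are not tuned afterwards.

## Known limitations

* 2D only; flows must be planar and shapes are assumed fully in focus.
* The origin correction is a rigid translation of the model shape; for
  spatially varying (tabulated) flow fields a true clamp-point shift
  would also change the load along the filament, an effect neglected as
  second-order for pixel-scale offsets.
* The erfc tip model assumes the profile decays with increasing x;
  profiles oriented the other way must be flipped by the caller.
* The exact softening test requires tie-free cycle means; ties fall back
  to the asymptotic approximation.
* `fit_kappa` cost is dominated by forward solves (~0.2 s per fit at 61
  nodes); fitting hundreds of replicates is minutes, not seconds.
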