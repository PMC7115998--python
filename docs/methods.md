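# Methods

This note records the models implemented in `nanodomain`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Hydrodynamic sizing model (`gsd`)

A bilayer-spanning lipid domain is treated as a rigid cylindrical inclusion
of diameter `d` in a thin viscous sheet (2D viscosity `η·h`, with `h` the
bilayer thickness) bounded by bulk water of viscosity `η_3D`. The classical
Saffman–Delbrück logarithmic mobility only holds for reduced radii
`ε = d·η_3D/(h·η) < 0.1`; micrometre-scale domains violate this, so the
package implements the Petrov–Schwille interpolation, accurate over
`10⁻³ < ε < 10³`:

    D(ε) = A · [ln(2/ε) − γ_e + 4ε/π − (ε²/2)·ln(2/ε)]
             / [1 − (ε³/π)·ln(2/ε) + v·ε^p / (1 + w·ε^q)]

with `A = k_BT/(4πhη)`, `ε = β·d/u`, `β = η_3D·u/(h·η)`, and fixed
interpolation constants γ_e = 0.5772, p = 2.74819, q = 0.61465,
v = 0.73761, w = 0.52119 (literals; constructing `GSDConstants` with other
values requires an explicit override flag). Key numerical properties,
all under test:

* strict monotone decrease of `D` in `d`, which makes the inversion
  `D → d` unique; the inversion is a bracketed (Brent) root search in
  log-diameter over `d ∈ [10⁻⁴, 10³] μm`, with the search interval widened
  by 5% in log-space so targets on the bracket edge still change sign;
  round-trip accuracy is ~10⁻⁹ relative, far inside the 10⁻⁶ contract;
* for `ε < 10⁻³` the law reverts to the classical
  `A(ln(2/ε) − γ_e + 4ε/π)` within 0.1%;
* evaluations outside `10⁻³ < ε < 10³` emit a `ValidityRangeWarning`
  rather than an error — the single-lipid extrapolation (`d` = 0.9 nm,
  ε ≈ 3×10⁻⁴) deliberately sits there, and the classical-limit agreement
  justifies it.

Units: lengths in μm except `h` (nm), `D` in μm²/s, viscosities in Pa·s,
`T` in K with k_B = 1.380649×10⁻²³ J/K; `k_BT` is recomputed from `T` on
every access, never cached. Default `T` = 295 K (room temperature),
`h` = 5 nm, `η_3D` = 10⁻³ Pa·s, `u` = 1 μm.

**Apparent-diameter offset.** Scan-speed motion blur plus diffraction make
the optical diameter `d_a` exceed the true one by a constant δ for
`d_a ≲ 1.7 μm`; `true_diameter` returns `d = d_a − δ` with quadrature-
propagated σ and flags (rather than clips) non-physical `d ≤ 0` results.

**Viscosity conversions.** Both single-parameter routes are exposed:
`η = k_BT/(4πhA)` from the prefactor, and `η = η_3D·u/(hβ)` from the
mobility ratio. With the two tracked-phase parameter sets
(A = 0.76 μm²/s, β = 0.33) and (A = 0.18, β = 0.20) these give 0.085 and
0.360 Pa·s from A — below the reference values 0.458/0.108 Pa·s quoted for
the two phases, whose exact derivation (possibly a joint A–β estimate) is
not stated in the source analysis. The package therefore reports both
conversions plus the consistency statistic `β·k_BT/(4π·u·A)` (an implied
`η_3D`, ≈1.4×10⁻⁴ and 3.6×10⁻⁴ Pa·s for the two rows — the A–β link is
only approximate in fitted data) and leaves the interpretation to the
analyst. A second ambiguity is deliberate: the "LOD" parameter row
describes ordered domains *moving through* the disordered phase, so its
viscosity conversions characterize the disordered continuous phase, and
vice versa.

## Track analysis (`tracking`)

Per-track, time-averaged MSD over all ordered frame pairs at integer lags
up to ⌊N/4⌋ (the tail has too few pairs to be useful). `D` comes from a
weighted least-squares line `MSD = 4Dτ + b` over lags 2–10, weights equal
to pair counts; lag 1 is excluded by default because static localization
noise dominates it, and the intercept `b` absorbs that noise (`b = 4σ_loc²`).
A negative fitted `D` is flagged and excluded downstream, never clipped —
clipping would bias ensemble means upward.

The simple-diffusion filter fits `log MSD` vs `log τ` over the same
window: a track passes when the anomalous exponent satisfies
`|α − 1| ≤ 0.2` and `r² ≥ 0.9`. The thresholds are this package's own
operating point: they pass ≥95% of pure Brownian tracks of ≥500 frames
while rejecting ballistic (α = 2) and confined (α < 0.8) motion, both
verified by simulation. Per-domain `σ_D` comes from a block bootstrap over
displacement blocks (10 displacements per block, 200 resamples, seeded) —
blocks, not single displacements, so the short-range correlation induced
by localization noise survives resampling.

## Mobility-law fitting (`gsdfit`)

`fit_gsd` estimates `(A, β, δ)` by bounded nonlinear least squares of
`D_i` against `model(d_a,i − δ)` with `A, β > 0` and `0 ≤ δ < min(d_a)`.
A and β are treated as independent parameters (their theoretical link is
a post-hoc check, above). The A–β–δ objective has a correlated valley, so
five seeded starts jittered ±50% around the initial point are run and the
best final objective wins, ties broken toward smaller δ. Default
initialization `A = median(D)/5`, `β = 0.3`, `δ = 0.8·min(d_a)` lands
within an order of magnitude of realistic values for both phases.

The default loss is on `D` directly, weighted by `1/σ_D²` when every
observation carries an uncertainty; a log-residual loss is available via
`log_space=True` and is the better-matched (maximum-likelihood) choice
when the dominant noise is multiplicative, as it is for MSD-derived `D`.
Two uncertainty routes are provided: linearization (Jacobian covariance,
t-based 95% intervals) in `GSDFitResult`, and case-resampling percentile
bootstrap (`bootstrap_fit`). The bootstrap is the recommended interval
for δ: at realistic noise the D-space estimator carries a second-order
small-sample bias in δ of order 2 SE (the model is strongly curved in δ
where `d_a − δ` is small), which linearized intervals do not see; the
log-space estimator is nearly unbiased and its bootstrap intervals show
~93% empirical coverage at nominal 95% in the recovery simulations.

Identifiability diagnostics: `delta_at_bound` marks δ pinned at
`min(d_a)`; `identifiable=False` marks a rank-deficient Jacobian at the
optimum (e.g. all domains the same size, where δ trades off exactly
against A and β); designs lacking small domains inflate the reported δ
standard error by orders of magnitude, which is the intended signal.

`smallest_domain` converts the smallest apparent diameter via the fitted
δ with quadrature-combined uncertainty; non-physical results are flagged.

## Registration energetics (`energetics`)

Domains are disks (perimeter πd, area πd²/4) — line tension keeps them
circular. Two registration driving forces are compared in k_BT units,
diameters in nm:

* rim energy `w_rim = π·d·Δγ`, with Δγ the line-tension gain per unit
  length of matched boundary; defaults Δγ_cis = 0.2 and
  Δγ_trans = 0.07 k_BT/nm for the two photoswitch states of the
  photoswitchable diacylglycerol that modulates the boundary;
* undulation coupling `W_area = w_area·π·d²/4` with
  `w_area = (1/4a²)·ln[(B_S+B_R)²/(4·B_S·B_R)]` for monolayer splay
  moduli B_R = 20, B_S = 10 k_BT and ultraviolet cutoff `a`.

They cross at `d* = 4Δγ/w_area`, an algebraic identity the property tests
check for randomized parameters. With the working value
w_area = 0.013 k_BT/nm², d*_cis ≈ 62 nm → 60 and d*_trans ≈ 22 → 20 nm:
small cis-state domains (40 nm) are rim-driven, large trans-state domains
(120 nm) undulation-driven.

Two documented inconsistencies among the conventional inputs are left
unresolved by design. First, the formula with `a` = 1 nm gives
w_area = 0.0295 k_BT/nm², while the working value 0.013 corresponds to
`a ≈ 1.505 nm`; since `a` is only known to be "of order 1 nm", both are
supported — `ElasticParams.w_area` defaults to the supplied 0.013 (and
every report records whether the density was supplied or computed), set
it to `None` to compute from the moduli. Second, the reference energies
(24.33, 8.33, 73.2, 25.2, 15.56, 144 k_BT) back-solve to unrounded inputs
(Δγ_cis ≈ 0.194, Δγ_trans ≈ 0.0663 k_BT/nm, w_area ≈ 0.0124–0.0127);
with the rounded defaults the computed energies land 2–6% high, which is
why tests compare them at 5% and treat the worst case
(π·40·0.07 = 8.80 vs 8.33, 5.6%) as a documented rounding artifact rather
than an assertion.

Monolayer hydrophobic thicknesses, the area-stretching modulus and the
spontaneous curvatures are carried as provenance metadata only: they are
inputs to the elastic theory that *produces* Δγ, which is out of scope
here — Δγ values are consumed as given.

## FCS cross-check (`fcs`)

Single-component free 2D diffusion through a Gaussian spot:
`G(τ) = G0/(1 + τ/τ_D)`, `D = r0²/(4τ_D)`. The beam waist `r0` is an
instrument calibration the curve itself cannot supply — `D` scales as
`r0²`, so FCS-derived values are only as good as the supplied waist
(default 0.2 μm, a typical confocal calibration). A fitted `τ_D` outside
the measured lag span is flagged as an extrapolation. Triplet kinetics
and anomalous exponents are out of scope. The consistency argument the
module supports: lipid-probe `D` measured by FCS in the disordered and
ordered phases (7.8 and 0.9 μm²/s as generator truths) should bracket the
single-lipid extrapolations of the two fitted mobility laws (6.26 and
1.57 μm²/s) — and does.

## Registration index (`registration`)

Ordered domains are segmented per channel by global Otsu threshold
(optionally after Gaussian smoothing), dim polarity by default since both
dyes partition into the disordered phase. Registration is scored as the
Jaccard overlap of the two masks — a set-overlap claim deserves a
set-overlap statistic, not an intensity correlation; mask-based Manders
fractions are secondary outputs. No channel alignment is performed:
simultaneously acquired channels are assumed pixel-registered. For
independent random masks with area fractions f₁, f₂ the index concentrates
at `f₁f₂/(f₁+f₂−f₁f₂)` (≈0.176 at f₁ = f₂ = 0.3), the calibration point
for "no registration"; fully registered synthetic pairs score ≥0.9 despite
PSF blur and shot noise, antiregistered ones ≤0.1.

## Synthetic data (`synthetic`)

Defaults are the study conditions: 29 ordered / 31 disordered tracked
domains; true diameters log-uniform over 0.04–20 μm (spanning the
smallest inferred domain to the largest optically tracked one); mobility
truths (A = 0.76 μm²/s, β = 0.33, δ = 0.57 μm) and (A = 0.18, β = 0.20,
δ = 0.46) for the two phases; `d_a = d + δ` exactly (the constant-offset
assumption is baked in and hence testable); frame interval 0.05 s with
400 frames per track, a typical confocal tracking budget long enough for
lag-2–10 MSD fits to resolve D at ~10% per track; localization noise
σ_loc = 0.02 μm, a typical centroid precision. Image mode places
non-overlapping disks (rejection sampling, 10⁴ attempts, ≤50% area) of
0.8–3 μm on a 256-px field at 0.1 μm/px, blurs with a 0.1 μm PSF and adds
Poisson noise at 200 photons per unit intensity; an `antiregistered_fraction`
puts that share of domains in only one channel. FCS mode evaluates the 2D
model on 64 log-spaced lags with 2% multiplicative noise.

What the generator does **not** emulate — and therefore what passing
tests cannot certify about real data: the physical origin of δ (blur is
injected as a constant, not simulated from scan geometry), domain growth,
shrinkage and coalescence during observation (all tracks are
size-invariant by construction), hydrodynamic or steric domain–domain
interactions, photobleaching and detector noise beyond Poisson statistics,
membrane-wide flows or drift, and any deviation of real boundary shapes
from circularity. Identical seeds give bit-identical outputs.

## Pipeline (`cli`, `io`)

Thin orchestration: `simulate | track | fit | energetics | fcs | register
| report`, global `--seed/--config/--out-dir/--log-level`, YAML config
overriding module defaults, CSV/TIFF in, JSON + Markdown out; CSV schema
violations name the offending column and exit nonzero. The per-phase fit
report includes both viscosity conversions, the implied-η_3D consistency
value, the single-lipid extrapolation at d = 0.9 nm and the
smallest-domain estimate, so the whole derived-number table comes from
one command sequence.

## Problem sizes in the test suite

Simulation-backed tests run at reduced but statistically meaningful
sizes chosen so the full suite stays fast while the assertions remain
sharp: 200-replicate recovery/coverage ensembles at the study's n = 29/31,
100-curve FCS noise sweeps, 100-track filter calibrations, 10⁴–10⁵-step
single-track checks, and 1000-draw energetics identity sweeps. All
stochastic tests are seeded; hypothesis property tests run derandomized.
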