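# nanodomain

Quantitative analysis of nanoscale ordered/disordered lipid domains in
freestanding bilayers: infer **true domain sizes from their mobility**,
back out membrane viscosities, cross-check with fluorescence correlation
spectroscopy, score **trans-leaflet domain registration** from two-channel
images, and evaluate the line-tension vs undulation energetics that explain
why even 40–120 nm domains sit in register across the two leaflets.

It is written for membrane biophysicists who track phase-separated domains
(liquid-ordered, LOD; liquid-disordered, LDD) by confocal microscopy and
want to go below the diffraction limit without super-resolution hardware.

## The model

Optically measured (apparent) domain diameters overestimate the true
diameter by a constant offset δ caused by scan-speed motion blur and
diffraction: `d = d_a − δ`. The mobility of a domain of true diameter `d`
in a bilayer of thickness `h` and viscosity `η` under water (viscosity
`η_3D`) follows the generalized Saffman–Delbrück law, valid for reduced
radii `ε = β·d/u` anywhere in `10⁻³ < ε < 10³` (with `β = η_3D·u/(h·η)`,
`u = 1 μm`):

```
D(ε) = A · [ln(2/ε) − γ_e + 4ε/π − (ε²/2)·ln(2/ε)]
         / [1 − (ε³/π)·ln(2/ε) + v·ε^p / (1 + w·ε^q)]
```

with `A = k_BT/(4πhη)` and fixed constants γ_e = 0.5772, p = 2.74819,
q = 0.61465, v = 0.73761, w = 0.52119. Fitting `(A, β, δ)` to per-domain
`(d_a, D)` observations — D estimated from the MSD of each track, after
filtering for simple diffusion — simultaneously calibrates the optical
offset and the membrane hydrodynamics, so the smallest resolvable domain
sizes land in the tens of nanometres.

Registration energetics: an unmatched domain rim costs `w_rim = π·d·Δγ`
(k_BT) while undulation-mediated coupling contributes
`W_area = w_area·π·d²/4` with
`w_area = (1/4a²)·ln[(B_S+B_R)²/(4·B_S·B_R)]`; the two cross at the
critical diameter `d* = 4Δγ/w_area`, below which line tension is the
dominant driving force for registration.

## Worked example

No downloads are needed: the `synthetic` module generates a full study —
29 ordered and 31 disordered tracked domains with true diameters spanning
0.04–20 μm — with the same statistical structure the analysis assumes.

```python
import warnings
from nanodomain import (ValidityRangeWarning, diffusion_coefficient,
                        energy_report, fit_gsd, smallest_domain,
                        viscosity_from_A, viscosity_from_beta)
from nanodomain.synthetic import SimulationConfig, simulate_tracks
from nanodomain.tracking import TrackingConfig, estimate_observations

trajs, truth = simulate_tracks(SimulationConfig(seed=7))
obs, excluded = estimate_observations(trajs, TrackingConfig(seed=7))
lod_obs = [o for o in obs if o.phase == "LOD"]
result = fit_gsd(lod_obs, seed=7)

p = result.params
print(f"A = {p.A:.3f} +/- {result.perr['A']:.3f} um^2/s")
print(f"beta = {p.beta:.3f} +/- {result.perr['beta']:.3f}")
print(f"delta = {p.delta:.3f} +/- {result.perr['delta']:.3f} um")
est = smallest_domain(result, lod_obs)
print(f"smallest true domain = {est.value*1000:.0f} +/- {est.sigma*1000:.0f} nm")
print(f"eta (from A) = {viscosity_from_A(p):.3f} Pa s, "
      f"eta (from beta) = {viscosity_from_beta(p):.3f} Pa s")
with warnings.catch_warnings():
    warnings.simplefilter("ignore", ValidityRangeWarning)
    print(f"single-lipid extrapolation D(0.9 nm) = "
          f"{diffusion_coefficient(0.9e-3, p):.2f} um^2/s")
r = energy_report(40.0, "cis")
print(f"40 nm cis domain: rim {r.w_rim:.1f} kBT vs undulation "
      f"{r.w_area_total:.1f} kBT -> {r.dominant}-driven (d* = {r.d_star:.0f} nm)")
```

prints

```
A = 0.777 +/- 0.139 um^2/s
beta = 0.347 +/- 0.089
delta = 0.543 +/- 0.053 um
smallest true domain = 69 +/- 53 nm
eta (from A) = 0.083 Pa s, eta (from beta) = 0.577 Pa s
single-lipid extrapolation D(0.9 nm) = 6.36 um^2/s
40 nm cis domain: rim 25.1 kBT vs undulation 16.3 kBT -> rim-driven (d* = 62 nm)
```

The fit recovers the generating truth (A = 0.76, β = 0.33, δ = 0.57)
within one standard error from 29 noisy tracks; subtracting the fitted δ
from the smallest apparent diameter sizes the smallest domain at ~70 nm —
far below the diffraction limit. The 40 nm domain sits below the ~60 nm
crossover, so its registration is driven by the rim term.

The same flow is available from a shell:

```sh
nanodomain --seed 7 --out-dir run simulate
nanodomain --seed 7 --out-dir run track --input run/trajectories.csv
nanodomain --seed 7 --out-dir run fit --input run/observations.csv
nanodomain --out-dir run energetics
nanodomain --out-dir run fcs --input run/fcs.csv
nanodomain --out-dir run register --ch1 run/channel1.tif --ch2 run/channel2.tif
nanodomain --out-dir run report        # merged report.json + report.md
```

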