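"""Synthetic study data with the statistical structure the analysis assumes.

Generates every input the pipeline consumes:

* **Tracks** — per-phase ensembles of size-invariant domains whose true
  diameters are log-uniform over the study's size span and whose mobility
  follows the generalized Saffman–Delbrück law; trajectories are Gaussian
  random walks with localization noise, and apparent diameters carry the
  constant per-phase offset δ (``d_a = d + δ``, size-independent below the
  resolution-limited regime — the same assumption the fit makes, so it is
  directly testable).
* **Images** — two-channel rasters of dim disk-shaped ordered domains on a
  bright disordered background, with Gaussian PSF blur and Poisson shot
  noise; a configurable fraction of domains appears in only one channel as
  an antiregistration control.  True masks are returned alongside.
* **FCS curves** — the 2D autocorrelation model evaluated on log-spaced
  lags with multiplicative Gaussian noise.

The generator injects δ as a constant per phase rather than modelling its
physical origins (scan-speed smear and diffraction); that matches how the
fit treats it.  Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fcs import FCSCurve, fcs_model
from .gsd import HydroParams, diffusion_coefficient
from .registration import ChannelPair
from .tracking import Trajectory

__all__ = [
    "DEFAULT_LOD_PARAMS",
    "DEFAULT_LDD_PARAMS",
    "SimulationConfig",
    "simulate_tracks",
    "simulate_images",
    "simulate_fcs",
]

#: Fitted hydrodynamic parameters for tracked ordered domains (LODs moving
#: through the disordered phase): A μm²/s, β, δ μm.
DEFAULT_LOD_PARAMS = HydroParams(A=0.76, beta=0.33, delta=0.57)

#: Fitted hydrodynamic parameters for tracked disordered domains (LDDs
#: moving through the ordered phase).
DEFAULT_LDD_PARAMS = HydroParams(A=0.18, beta=0.20, delta=0.46)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the study design: 29 tracked ordered and 31 tracked
    disordered domains, true diameters spanning 0.04–20 μm, mobility from
    the per-phase hydrodynamic parameter sets above.
    """

    seed: int = 0
    # --- tracks ------------------------------------------------------------
    n_lod: int = 29
    n_ldd: int = 31
    d_lo: float = 0.04          # μm, smallest true diameter
    d_hi: float = 20.0          # μm, largest true diameter
    lod_params: HydroParams = DEFAULT_LOD_PARAMS
    ldd_params: HydroParams = DEFAULT_LDD_PARAMS
    dt: float = 0.05            # s, frame interval
    n_frames: int = 400
    sigma_loc: float = 0.02     # μm, static localization noise
    # --- images ------------------------------------------------------------
    field_px: int = 256
    pixel_size: float = 0.1     # μm/px
    n_image_domains: int = 12
    image_d_lo: float = 0.8     # μm, domain diameters in image mode
    image_d_hi: float = 3.0
    psf_sigma: float = 0.1      # μm, Gaussian PSF width
    photons: float = 200.0      # Poisson scaling (photons at unit intensity)
    antiregistered_fraction: float = 0.0
    dim_level: float = 0.2      # relative intensity inside ordered domains
    bright_level: float = 1.0
    # --- FCS ---------------------------------------------------------------
    fcs_G0: float = 0.1
    fcs_r0: float = 0.2         # μm, beam waist
    fcs_noise: float = 0.02     # multiplicative noise on G
    fcs_n_points: int = 64

    def __post_init__(self) -> None:
        if self.d_lo <= 0 or self.d_hi < self.d_lo:
            raise ValueError("need 0 < d_lo <= d_hi")
        for name in ("dt", "sigma_loc", "pixel_size", "psf_sigma", "photons",
                     "fcs_G0", "fcs_r0"):
            if getattr(self, name) < 0 or (name in ("dt", "pixel_size",
                                                    "fcs_r0")
                                           and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.antiregistered_fraction <= 1.0:
            raise ValueError("antiregistered_fraction must be in [0, 1]")


def _draw_diameters(rng: np.random.Generator, n: int, lo: float,
                    hi: float) -> np.ndarray:
    if lo == hi:
        return np.full(n, lo)
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))


def simulate_tracks(config: SimulationConfig | None = None):
    """Simulate per-domain trajectories plus a ground-truth table.

    Returns ``(trajectories, truth)`` where ``truth`` is a DataFrame with
    one row per track: true diameter ``d_um``, model diffusion coefficient
    ``D_um2_s``, offset ``delta_um``, apparent diameter ``d_a_um``, phase.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    trajectories: list[Trajectory] = []
    rows = []
    specs = [("LOD", config.n_lod, config.lod_params),
             ("LDD", config.n_ldd, config.ldd_params)]
    for phase, n, params in specs:
        diameters = _draw_diameters(rng, n, config.d_lo, config.d_hi)
        for i, d in enumerate(diameters):
            D_true = diffusion_coefficient(float(d), params)
            steps = rng.normal(0.0, math.sqrt(2.0 * D_true * config.dt),
                               size=(config.n_frames - 1, 2))
            pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
            if config.sigma_loc > 0:
                pos = pos + rng.normal(0.0, config.sigma_loc, size=pos.shape)
            times = np.arange(config.n_frames) * config.dt
            d_a = float(d) + params.delta
            trajectories.append(Trajectory(
                track_id=f"{phase}_{i:03d}", times=times, positions=pos,
                d_a=d_a, phase=phase))
            rows.append({"track_id": f"{phase}_{i:03d}", "phase": phase,
                         "d_um": float(d), "D_um2_s": D_true,
                         "delta_um": params.delta, "d_a_um": d_a})
    truth = pd.DataFrame(rows)
    return trajectories, truth


def _place_disks(rng: np.random.Generator, config: SimulationConfig):
    """Non-overlapping disk centers/radii (px) by rejection sampling."""
    n_px = config.field_px
    radii_um = _draw_diameters(rng, config.n_image_domains,
                               config.image_d_lo, config.image_d_hi) / 2.0
    radii = radii_um / config.pixel_size
    total_area = float(np.sum(math.pi * radii**2))
    if total_area > 0.5 * n_px * n_px:
        raise ValueError(
            f"requested domain area ({total_area:.0f} px²) exceeds 50% of "
            f"the {n_px}×{n_px} field"
        )
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for r in sorted(radii, reverse=True):
        for attempt in range(10_000):
            c = rng.uniform(r, n_px - r, size=2)
            if all(np.hypot(c[0] - c0, c[1] - c1) > r + r0 + 1
                   for (c0, c1), r0 in zip(centers, placed_r)):
                centers.append((float(c[0]), float(c[1])))
                placed_r.append(float(r))
                break
        else:
            raise RuntimeError(
                "could not place non-overlapping domains in 10,000 attempts")
    return centers, placed_r


def _disk_mask(n_px: int, center, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n_px, 0:n_px]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def simulate_images(config: SimulationConfig | None = None):
    """Simulate a two-channel image of registered (or not) ordered domains.

    Returns ``(pair, mask1, mask2)`` — the noisy :class:`ChannelPair` and
    the per-channel ground-truth domain masks.  With antiregistered
    fraction f, ⌈f·n⌉ domains are present in only one channel, alternating
    between the two.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    n_px = config.field_px
    centers, radii = _place_disks(rng, config)
    n = len(centers)
    n_anti = int(round(config.antiregistered_fraction * n))
    mask1 = np.zeros((n_px, n_px), dtype=bool)
    mask2 = np.zeros((n_px, n_px), dtype=bool)
    for i, (c, r) in enumerate(zip(centers, radii)):
        disk = _disk_mask(n_px, c, r)
        if i < n_anti:
            (mask1 if i % 2 == 0 else mask2)[disk] = True
        else:
            mask1[disk] = True
            mask2[disk] = True

    from skimage.filters import gaussian  # local: optional heavy import path

    sigma_px = config.psf_sigma / config.pixel_size
    channels = []
    for mask in (mask1, mask2):
        img = np.where(mask, config.dim_level, config.bright_level)
        if sigma_px > 0:
            img = gaussian(img, sigma=sigma_px, preserve_range=True)
        if config.photons > 0:
            img = rng.poisson(img * config.photons) / config.photons
        channels.append(img.astype(float))
    pair = ChannelPair(channel1=channels[0], channel2=channels[1],
                       pixel_size=config.pixel_size)
    return pair, mask1, mask2


def simulate_fcs(config: SimulationConfig | None = None, *,
                 D: float = 7.8, tau_lo: float = 1e-6,
                 tau_hi: float = 1.0) -> FCSCurve:
    """Synthetic autocorrelation curve for a tracer of diffusivity D μm²/s.

    τ_D = r0²/(4D) is embedded via the 2D model; multiplicative Gaussian
    noise of relative amplitude ``config.fcs_noise`` is applied.
    """
    if config is None:
        config = SimulationConfig()
    if D <= 0:
        raise ValueError("D must be positive")
    rng = np.random.default_rng(config.seed)
    tau_D = config.fcs_r0**2 / (4.0 * D)
    taus = np.logspace(math.log10(tau_lo), math.log10(tau_hi),
                       config.fcs_n_points)
    G = fcs_model(taus, config.fcs_G0, tau_D)
    if config.fcs_noise > 0:
        G = G * (1.0 + rng.normal(0.0, config.fcs_noise, size=G.shape))
        sigma = config.fcs_noise * fcs_model(taus, config.fcs_G0, tau_D)
        return FCSCurve(taus=taus, G=G, sigma_G=sigma)
    return FCSCurve(taus=taus, G=G)
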