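"""Fluorescence correlation spectroscopy: 2D single-component model fits.

For free 2D diffusion through a Gaussian confocal spot of 1/e² beam waist
r0, the intensity autocorrelation decays as

    G(τ) = G0 / (1 + τ/τ_D),        D = r0² / (4·τ_D).

Used as an independent cross-check of single-lipid diffusion coefficients
extrapolated from domain mobility.  Triplet kinetics and anomalous exponents
are out of scope.

The beam waist is an instrument calibration, not a fit parameter: D scales
as r0², so FCS-derived diffusion coefficients are only as accurate as the
supplied r0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["FCSCurve", "FCSFit", "fcs_model", "fit_fcs"]

DEFAULT_BEAM_WAIST = 0.2  # μm, typical confocal calibration


@dataclass(frozen=True)
class FCSCurve:
    """An autocorrelation curve G(τ); τ in s, log-spaced lags allowed."""

    taus: np.ndarray
    G: np.ndarray
    sigma_G: np.ndarray | None = None

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float)
        G = np.asarray(self.G, dtype=float)
        object.__setattr__(self, "taus", taus)
        object.__setattr__(self, "G", G)
        if self.sigma_G is not None:
            object.__setattr__(self, "sigma_G",
                               np.asarray(self.sigma_G, dtype=float))
        if np.any(taus <= 0) or np.any(np.diff(taus) <= 0):
            raise ValueError("taus must be positive and strictly increasing")
        if not np.all(np.isfinite(G)):
            raise ValueError("G must be finite")


@dataclass(frozen=True)
class FCSFit:
    G0: float
    tau_D: float       # s
    D: float           # μm²/s
    r0: float          # μm
    tau_D_in_span: bool


def fcs_model(tau, G0: float, tau_D: float):
    """Single-component 2D diffusion autocorrelation G0/(1 + τ/τ_D)."""
    if G0 <= 0 or tau_D <= 0:
        raise ValueError("G0 and tau_D must be positive")
    tau = np.asarray(tau, dtype=float)
    G = G0 / (1.0 + tau / tau_D)
    return G if G.ndim else float(G)


def fit_fcs(curve: FCSCurve, r0: float = DEFAULT_BEAM_WAIST) -> FCSFit:
    """Least-squares fit of the 2D model; D = r0²/(4·τ_D).

    Requires ≥ 5 points.  A fitted τ_D outside the measured lag span is
    flagged (``tau_D_in_span=False``) — the decay was not sampled and D is
    an extrapolation.
    """
    if len(curve.taus) < 5:
        raise ValueError(
            f"fit_fcs needs >= 5 points spanning the decay, got "
            f"{len(curve.taus)}"
        )
    if r0 <= 0:
        raise ValueError("beam waist r0 must be positive")
    G0_init = float(np.max(curve.G))
    if G0_init <= 0:
        G0_init = 1.0
    # initial tau_D: lag where G first drops below half of its maximum
    below = np.where(curve.G <= G0_init / 2.0)[0]
    tau_D_init = float(curve.taus[below[0]]) if below.size else float(
        np.median(curve.taus))

    def model(tau, G0, tau_D):
        return G0 / (1.0 + tau / tau_D)

    popt, _ = curve_fit(
        model, curve.taus, curve.G, p0=[G0_init, tau_D_init],
        sigma=curve.sigma_G, absolute_sigma=curve.sigma_G is not None,
        bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=10000,
    )
    G0, tau_D = (float(v) for v in popt)
    D = r0**2 / (4.0 * tau_D)
    in_span = bool(curve.taus[0] <= tau_D <= curve.taus[-1])
    return FCSFit(G0=G0, tau_D=tau_D, D=D, r0=r0, tau_D_in_span=in_span)
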