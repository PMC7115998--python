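"""Generalized Saffman–Delbrück (GSD) hydrodynamics of membrane inclusions.

The classical Saffman–Delbrück model describes lateral diffusion of a
cylindrical inclusion of diameter ``d`` in a thin viscous sheet (the lipid
bilayer, 2D viscosity ``η·h``) bounded by bulk water (3D viscosity ``η_3D``).
Its validity is limited to small reduced radii ``ε = d·η_3D/(h·η) < 0.1``.
Micrometre-sized lipid domains violate that bound, so this module implements
the generalized form (Petrov–Schwille interpolation), accurate over
``1e-3 < ε < 1e3``:

    D(ε) = A · [ln(2/ε) − γ_e + 4ε/π − (ε²/2)·ln(2/ε)]
             / [1 − (ε³/π)·ln(2/ε) + v·ε^p / (1 + w·ε^q)]

with ``A = k_BT/(4πhη)`` and ``ε = β·d/u`` where ``β = η_3D·u/(h·η)`` for a
reference length ``u`` (1 μm by convention).  Optically measured (apparent)
domain diameters ``d_a`` exceed the true diameter by a constant offset δ
(scan-speed motion blur plus diffraction), so ``d = d_a − δ``.

Units: lengths in μm except the bilayer thickness ``h`` (nm); D in μm²/s;
viscosities in Pa·s; temperature in K; energies derived via k_B in J/K.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "K_B",
    "EPSILON_VALIDITY",
    "DIAMETER_BRACKET",
    "ValidityRangeWarning",
    "GSDConstants",
    "HydroParams",
    "DiameterEstimate",
    "reduced_radius",
    "diffusion_coefficient",
    "invert_diameter",
    "viscosity_from_A",
    "viscosity_from_beta",
    "eta3d_consistency",
    "true_diameter",
]

#: Boltzmann constant, J/K (2019 SI exact value).
K_B = 1.380649e-23

#: Reduced-radius range over which the generalized law was established.
EPSILON_VALIDITY = (1e-3, 1e3)

#: True-diameter bracket (μm) used for numerical inversion of D(d).
DIAMETER_BRACKET = (1e-4, 1e3)

_CANONICAL_CONSTANTS = (0.5772, 2.74819, 0.61465, 0.73761, 0.52119)


class ValidityRangeWarning(UserWarning):
    """Reduced radius ε falls outside the established validity range."""


@dataclass(frozen=True)
class GSDConstants:
    """Fixed numerical constants of the generalized Saffman–Delbrück law.

    ``w_c`` is the interpolation constant usually printed as ``w``; it is
    renamed here to avoid collision with rim energies elsewhere in the
    package.  The values are literals of the published interpolation formula;
    constructing the object with different values requires ``allow_override``.
    """

    gamma_e: float = 0.5772
    p: float = 2.74819
    q: float = 0.61465
    v: float = 0.73761
    w_c: float = 0.52119
    allow_override: bool = False

    def __post_init__(self) -> None:
        values = (self.gamma_e, self.p, self.q, self.v, self.w_c)
        if values != _CANONICAL_CONSTANTS and not self.allow_override:
            raise ValueError(
                "GSDConstants are fixed literals "
                f"{_CANONICAL_CONSTANTS}; pass allow_override=True to "
                "deliberately use non-standard values"
            )


DEFAULT_CONSTANTS = GSDConstants()


@dataclass(frozen=True)
class HydroParams:
    """Hydrodynamic parameter set governing the GSD diffusion law.

    Parameters
    ----------
    A
        Diffusivity scale ``k_BT/(4πhη)``, μm²/s.
    beta
        Dimensionless mobility ratio ``β = η_3D·u/(h·η)``.
    delta
        Apparent-diameter offset δ, μm.  Optically measured diameters
        overestimate the true diameter by this constant.
    u
        Reference length, μm.
    h
        Bilayer thickness, nm.
    eta3d
        Bulk water viscosity, Pa·s.
    T
        Absolute temperature, K.
    """

    A: float
    beta: float
    delta: float = 0.0
    u: float = 1.0
    h: float = 5.0
    eta3d: float = 1.0e-3
    T: float = 295.0

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.beta > 0 and self.u > 0 and self.h > 0
                and self.eta3d > 0 and self.T > 0):
            raise ValueError(
                "HydroParams requires A, beta, u, h, eta3d, T > 0; got "
                f"A={self.A}, beta={self.beta}, u={self.u}, h={self.h}, "
                f"eta3d={self.eta3d}, T={self.T}"
            )
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")

    @property
    def kBT(self) -> float:
        """Thermal energy k_B·T in J, computed from T on every access."""
        return K_B * self.T


@dataclass(frozen=True)
class DiameterEstimate:
    """A diameter with propagated 1σ uncertainty and a physicality flag."""

    value: float
    sigma: float = 0.0
    physical: bool = True

    def __iter__(self):
        return iter((self.value, self.sigma))


def reduced_radius(d, params: HydroParams, *, warn: bool = True):
    """Reduced radius ``ε = β·d/u`` of an inclusion of true diameter ``d`` μm.

    Equivalently ``ε = d·η_3D/(h·η)``.  A :class:`ValidityRangeWarning` is
    emitted when a nonzero ε falls outside ``EPSILON_VALIDITY``; evaluation
    proceeds regardless (single-lipid extrapolation deliberately sits at
    ε ≈ 3e-4).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("true diameter d must be >= 0")
    eps = params.beta * d / params.u
    if warn:
        flat = np.atleast_1d(eps)
        out = flat[(flat > 0) & ((flat < EPSILON_VALIDITY[0]) | (flat > EPSILON_VALIDITY[1]))]
        if out.size:
            warnings.warn(
                f"reduced radius ε={out[0]:.3g} outside validity range "
                f"[{EPSILON_VALIDITY[0]:g}, {EPSILON_VALIDITY[1]:g}]",
                ValidityRangeWarning,
                stacklevel=2,
            )
    return eps if eps.ndim else float(eps)


def diffusion_coefficient(d, params: HydroParams,
                          consts: GSDConstants = DEFAULT_CONSTANTS):
    """Generalized Saffman–Delbrück diffusion coefficient D(d), μm²/s.

    Strictly decreasing in ``d`` for any valid parameter set; reduces to the
    classical ``A·(ln(2/ε) − γ_e)`` for ε → 0.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr <= 0):
        raise ValueError("true diameter d must be > 0 for diffusion_coefficient")
    eps = params.beta * d_arr / params.u
    log_term = np.log(2.0 / eps)
    num = log_term - consts.gamma_e + 4.0 * eps / np.pi - 0.5 * eps**2 * log_term
    den = (1.0 - eps**3 / np.pi * log_term
           + consts.v * eps**consts.p / (1.0 + consts.w_c * eps**consts.q))
    D = params.A * num / den
    return D if D.ndim else float(D)


def invert_diameter(D: float, params: HydroParams,
                    consts: GSDConstants = DEFAULT_CONSTANTS) -> float:
    """True diameter d (μm) such that ``diffusion_coefficient(d) == D``.

    Uses bracketed root finding in log-diameter over ``DIAMETER_BRACKET``;
    monotonicity of the law makes the root unique.  Raises ``ValueError``
    naming the attainable interval when ``D`` lies outside it.
    """
    d_lo, d_hi = DIAMETER_BRACKET
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ValidityRangeWarning)
        D_max = diffusion_coefficient(d_lo, params, consts)
        D_min = diffusion_coefficient(d_hi, params, consts)
    if not (D_min <= D <= D_max):
        raise ValueError(
            f"D={D:g} μm²/s is unattainable: the GSD law on "
            f"d ∈ [{d_lo:g}, {d_hi:g}] μm spans [{D_min:.6g}, {D_max:.6g}] μm²/s"
        )

    def f(log_d: float) -> float:
        return diffusion_coefficient(math.exp(log_d), params, consts) - D

    # search slightly beyond the nominal bracket so a target sitting exactly
    # on an endpoint still changes sign inside the interval
    log_root = brentq(f, math.log(d_lo) - 0.05, math.log(d_hi) + 0.05,
                      xtol=1e-14, rtol=1e-15)
    return math.exp(log_root)


def viscosity_from_A(params: HydroParams) -> float:
    """Membrane viscosity η (Pa·s) implied by the prefactor A = k_BT/(4πhη)."""
    h_m = params.h * 1e-9
    A_m2s = params.A * 1e-12
    return params.kBT / (4.0 * math.pi * h_m * A_m2s)


def viscosity_from_beta(params: HydroParams) -> float:
    """Membrane viscosity η (Pa·s) implied by β = η_3D·u/(h·η)."""
    u_m = params.u * 1e-6
    h_m = params.h * 1e-9
    return params.eta3d * u_m / (h_m * params.beta)


def eta3d_consistency(params: HydroParams) -> float:
    """Implied bulk viscosity ``β·k_BT/(4π·u·A)`` in Pa·s.

    A and β are fitted independently, but in theory they are linked through
    the bulk water viscosity; comparing the return value with ``params.eta3d``
    quantifies the internal consistency of a fit.
    """
    u_m = params.u * 1e-6
    A_m2s = params.A * 1e-12
    return params.beta * params.kBT / (4.0 * math.pi * u_m * A_m2s)


def true_diameter(d_a: float, delta: float, *, sigma_da: float = 0.0,
                  sigma_delta: float = 0.0) -> DiameterEstimate:
    """True diameter ``d = d_a − δ`` with quadrature-propagated uncertainty.

    A non-positive result is returned flagged (``physical=False``) rather
    than clipped, so downstream code can decide how to treat domains whose
    apparent size is indistinguishable from the offset.
    """
    d = d_a - delta
    sigma = math.hypot(sigma_da, sigma_delta)
    return DiameterEstimate(value=d, sigma=sigma, physical=d > 0)
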