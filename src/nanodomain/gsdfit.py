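"""Fitting the generalized Saffman–Delbrück law with a diameter offset.

Given per-domain observations of apparent diameter ``d_a`` and diffusion
coefficient ``D``, estimate the three parameters of the mobility model,

    D_i = GSD(d_a,i − δ; A, β),

by bounded nonlinear least squares.  A and β are treated as independent
parameters (their theoretical link through the bulk viscosity serves as a
post-hoc consistency check, see :func:`nanodomain.gsd.eta3d_consistency`).
The offset δ is the same for every domain of a phase: motion blur and
diffraction inflate all apparent diameters by a constant amount.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .gsd import (
    DEFAULT_CONSTANTS,
    DiameterEstimate,
    GSDConstants,
    HydroParams,
    ValidityRangeWarning,
    diffusion_coefficient,
    true_diameter,
)

__all__ = [
    "DomainObservation",
    "GSDFitResult",
    "fit_gsd",
    "bootstrap_fit",
    "corrected_curve",
    "smallest_domain",
]

_PARAM_NAMES = ("A", "beta", "delta")


@dataclass(frozen=True)
class DomainObservation:
    """One tracked domain: apparent diameter, mobility, and phase label."""

    d_a: float
    D: float
    sigma_D: float | None = None
    phase: str = "unknown"

    def __post_init__(self) -> None:
        if not (self.d_a > 0 and self.D > 0):
            raise ValueError(
                f"DomainObservation requires d_a > 0 and D > 0, got "
                f"d_a={self.d_a}, D={self.D}"
            )


@dataclass
class GSDFitResult:
    """Point estimates, covariance and 95% CIs of (A, β, δ).

    ``identifiable`` is False when the Jacobian at the optimum is rank
    deficient — e.g. when every domain has the same apparent size, so the
    offset δ cannot be separated from (A, β).
    """

    params: HydroParams
    cov: np.ndarray
    ci95: dict[str, tuple[float, float]]
    perr: dict[str, float]
    cost: float
    converged: bool
    delta_at_bound: bool
    identifiable: bool
    n_obs: int
    weighted: bool
    residuals: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "A": self.params.A,
            "beta": self.params.beta,
            "delta": self.params.delta,
            "perr": dict(self.perr),
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "cost": float(self.cost),
            "converged": bool(self.converged),
            "delta_at_bound": bool(self.delta_at_bound),
            "identifiable": bool(self.identifiable),
            "n_obs": int(self.n_obs),
            "weighted": bool(self.weighted),
        }


def _residuals(theta: np.ndarray, d_a: np.ndarray, D: np.ndarray,
               sigma: np.ndarray | None, log_space: bool,
               template: HydroParams, consts: GSDConstants) -> np.ndarray:
    A, beta, delta = theta
    d = np.maximum(d_a - delta, 1e-12)
    p = HydroParams(A=A, beta=beta, delta=delta, u=template.u, h=template.h,
                    eta3d=template.eta3d, T=template.T)
    model = diffusion_coefficient(d, p, consts)
    if log_space:
        r = np.log(model) - np.log(D)
    else:
        r = model - D
    if sigma is not None:
        r = r / sigma
    return r


def fit_gsd(obs, init: HydroParams | None = None, *,
            bounds: tuple | None = None,
            consts: GSDConstants = DEFAULT_CONSTANTS,
            log_space: bool = False,
            n_starts: int = 5,
            seed: int = 0) -> GSDFitResult:
    """Fit (A, β, δ) of the offset GSD law to domain observations.

    Parameters
    ----------
    obs
        Sequence of :class:`DomainObservation` (≥ 4; the model has three
        parameters).
    init
        Starting parameter set.  Default: ``A = median(D)/5``, ``β = 0.3``,
        ``δ = 0.8·min(d_a)``.
    bounds
        ``(lower, upper)`` triples for (A, β, δ).  Default: A, β > 0 and
        ``0 ≤ δ < min(d_a)``.
    log_space
        Fit residuals on log D instead of D.
    n_starts
        Multi-start count; starts are jittered ±50% around ``init`` to guard
        against the correlated A–β–δ valley.  Best final objective wins,
        ties broken in favour of smaller δ.

    The objective is weighted by ``1/σ_D²`` when every observation carries
    ``sigma_D``, unweighted otherwise.
    """
    obs = list(obs)
    if len(obs) < 4:
        raise ValueError(f"fit_gsd needs >= 4 observations, got {len(obs)}")
    d_a = np.array([o.d_a for o in obs])
    D = np.array([o.D for o in obs])
    sigmas = [o.sigma_D for o in obs]
    weighted = all(s is not None and s > 0 for s in sigmas)
    sigma = np.array(sigmas, dtype=float) if weighted else None

    d_a_min = float(d_a.min())
    if init is None:
        init = HydroParams(A=float(np.median(D)) / 5.0, beta=0.3,
                           delta=0.8 * d_a_min)
    if bounds is None:
        lower = np.array([1e-12, 1e-12, 0.0])
        upper = np.array([np.inf, np.inf, d_a_min * (1.0 - 1e-9)])
    else:
        lower, upper = (np.asarray(b, dtype=float) for b in bounds)

    x0 = np.array([init.A, init.beta, init.delta])
    x0 = np.clip(x0, lower + 1e-15, np.where(np.isfinite(upper), upper, x0))

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        jitter = rng.uniform(0.5, 1.5, size=3)
        starts.append(np.clip(x0 * jitter, lower + 1e-15,
                              np.where(np.isfinite(upper), upper, x0 * jitter)))

    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ValidityRangeWarning)
        for x_start in starts:
            try:
                res = least_squares(
                    _residuals, x_start, bounds=(lower, upper),
                    args=(d_a, D, sigma, log_space, init, consts),
                    method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost - 1e-15 or (
                    abs(res.cost - best.cost) <= 1e-15 and res.x[2] < best.x[2]):
                best = res
    if best is None or not best.success:
        raise RuntimeError(
            "GSD fit did not converge"
            + ("" if best is None else f"; best point {best.x}, cost {best.cost:g}")
        )

    A_hat, beta_hat, delta_hat = best.x
    delta_at_bound = bool(upper[2] - delta_hat < 1e-6 * max(upper[2], 1.0))

    n, p = len(obs), 3
    dof = max(n - p, 1)
    s2 = 2.0 * best.cost / dof
    sv = np.linalg.svd(best.jac, compute_uv=False)
    identifiable = bool(sv[-1] > 1e-8 * sv[0])
    JTJ = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(JTJ) * s2
    except np.linalg.LinAlgError:
        cov = np.full((3, 3), np.nan)
    perr = {name: float(np.sqrt(max(cov[i, i], 0.0)))
            for i, name in enumerate(_PARAM_NAMES)}
    tcrit = stats.t.ppf(0.975, dof)
    point = dict(zip(_PARAM_NAMES, best.x))
    ci95 = {name: (point[name] - tcrit * perr[name],
                   point[name] + tcrit * perr[name])
            for name in _PARAM_NAMES}

    fitted = HydroParams(A=float(A_hat), beta=float(beta_hat),
                         delta=float(delta_hat), u=init.u, h=init.h,
                         eta3d=init.eta3d, T=init.T)
    return GSDFitResult(params=fitted, cov=cov, ci95=ci95, perr=perr,
                        cost=float(best.cost), converged=bool(best.success),
                        delta_at_bound=delta_at_bound,
                        identifiable=identifiable, n_obs=n,
                        weighted=weighted, residuals=best.fun)


def bootstrap_fit(obs, *, n_boot: int = 500, seed: int = 0,
                  max_fail_fraction: float = 0.2,
                  **fit_kwargs) -> dict[str, tuple[float, float]]:
    """Case-resampling bootstrap percentile 95% CIs for (A, β, δ).

    Raises if the full-data fit fails or more than ``max_fail_fraction`` of
    resample refits fail.
    """
    if n_boot <= 0:
        raise ValueError(f"n_boot must be positive, got {n_boot}")
    obs = list(obs)
    full = fit_gsd(obs, seed=seed, **fit_kwargs)
    init = full.params
    rng = np.random.default_rng(seed)
    draws = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(obs), size=len(obs))
        sample = [obs[i] for i in idx]
        try:
            # refit from the full-data optimum; single start keeps this cheap
            r = fit_gsd(sample, init=init, n_starts=1, seed=seed, **fit_kwargs)
            draws.append([r.params.A, r.params.beta, r.params.delta])
        except Exception:
            failures += 1
    if failures > max_fail_fraction * n_boot:
        raise RuntimeError(
            f"bootstrap_fit: {failures}/{n_boot} refits failed "
            f"(limit {max_fail_fraction:.0%})"
        )
    draws = np.asarray(draws)
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    return {name: (float(lo[i]), float(hi[i]))
            for i, name in enumerate(_PARAM_NAMES)}


def corrected_curve(result: GSDFitResult, d_grid,
                    obs=None,
                    consts: GSDConstants = DEFAULT_CONSTANTS) -> pd.DataFrame:
    """Model curve D(d) over a true-diameter grid after offset correction.

    When ``obs`` is given, the observations are appended with their apparent
    diameters shifted by the fitted δ (``d = d_a − δ``), reproducing the
    replot of mobility versus true size.
    """
    d_grid = np.atleast_1d(np.asarray(d_grid, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ValidityRangeWarning)
        D_model = np.atleast_1d(
            diffusion_coefficient(d_grid, result.params, consts))
    frame = pd.DataFrame({"d_um": d_grid, "D_um2_s": D_model,
                          "kind": "model"})
    if obs is not None:
        delta = result.params.delta
        rows = pd.DataFrame({
            "d_um": [o.d_a - delta for o in obs],
            "D_um2_s": [o.D for o in obs],
            "kind": "observation",
        })
        frame = pd.concat([frame, rows], ignore_index=True)
    return frame


def smallest_domain(result: GSDFitResult, obs, *,
                    sigma_da: float = 0.0) -> DiameterEstimate:
    """Smallest true domain diameter in a set: ``min(d_a) − δ`` ± σ.

    The uncertainty combines the (optional) apparent-diameter uncertainty
    with the fitted standard error of δ in quadrature.  A non-positive
    estimate comes back flagged rather than clipped.
    """
    obs = list(obs)
    if not obs:
        raise ValueError("smallest_domain requires at least one observation")
    d_a_min = min(o.d_a for o in obs)
    return true_diameter(d_a_min, result.params.delta,
                         sigma_da=sigma_da, sigma_delta=result.perr["delta"])
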