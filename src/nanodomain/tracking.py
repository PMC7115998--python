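"""Single-particle tracking statistics: MSD curves, diffusion fits, filters.

Each tracked domain yields a 2D trajectory sampled at a uniform frame
interval.  The time-averaged mean squared displacement (MSD) at lag τ = k·dt,

    MSD(k·dt) = ⟨ |r(t + k·dt) − r(t)|² ⟩_t ,

grows as 4Dτ + b for simple (Brownian) diffusion, where the intercept b
absorbs static localization noise (b = 4σ_loc²).  Domains whose motion is
not compatible with simple diffusion — directed drift, confinement — are
filtered out before the mobility-versus-size analysis via the anomalous
exponent α of a log-log fit (α ≈ 1 for simple diffusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gsdfit import DomainObservation

__all__ = [
    "Trajectory",
    "MSDCurve",
    "DiffusionFit",
    "SimpleDiffusionVerdict",
    "TrackingConfig",
    "compute_msd",
    "fit_diffusion",
    "classify_simple_diffusion",
    "estimate_observations",
]


@dataclass(frozen=True)
class Trajectory:
    """A single domain's time-stamped 2D track (μm, s)."""

    track_id: str
    times: np.ndarray
    positions: np.ndarray
    d_a: float | None = None
    phase: str = "unknown"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)
        if times.ndim != 1 or len(times) < 2:
            raise ValueError("Trajectory needs >= 2 time points")
        if positions.shape != (len(times), 2):
            raise ValueError(
                f"positions must have shape (n, 2) matching times; got "
                f"{positions.shape} for {len(times)} times"
            )
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(positions))):
            raise ValueError("Trajectory contains non-finite values")
        dts = np.diff(times)
        if np.any(dts <= 0):
            raise ValueError("times must be strictly increasing")
        dt = dts[0]
        if np.any(np.abs(dts - dt) > 1e-9 * dt):
            raise ValueError(
                "frame interval must be uniform to 1e-9 relative; "
                "resampling is out of scope"
            )

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class MSDCurve:
    """Time-averaged MSD per integer lag, with pair counts."""

    lags: np.ndarray    # τ, s; strictly increasing
    msd: np.ndarray     # μm²
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        for name in ("lags", "msd", "n_pairs"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if np.any(self.msd < 0):
            raise ValueError("msd must be >= 0")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(np.diff(self.n_pairs) > 0):
            raise ValueError("n_pairs must be non-increasing in lag")


@dataclass(frozen=True)
class DiffusionFit:
    D: float          # μm²/s, may be negative (flagged, never clipped)
    intercept: float  # μm²; 4σ_loc² for pure localization noise
    r2: float
    n_lags: int
    negative_D: bool


@dataclass(frozen=True)
class SimpleDiffusionVerdict:
    is_simple: bool
    alpha: float
    r2: float


@dataclass
class TrackingConfig:
    """Thresholds and windows for the per-track analysis.

    ``fit_window`` is an inclusive range of integer lags; lag 1 is excluded
    by default because localization noise dominates it.
    """

    max_lag_fraction: float = 0.25
    fit_window: tuple[int, int] = (2, 10)
    alpha_tol: float = 0.2
    r2_min: float = 0.9
    n_boot: int = 200
    boot_block: int = 10
    seed: int = 0


def compute_msd(traj: Trajectory, max_lag_fraction: float = 0.25) -> MSDCurve:
    """Time-averaged MSD over all ordered frame pairs at each integer lag.

    Lags run from 1 to ⌊N·max_lag_fraction⌋ frames (at least 2 lags are
    required; short tracks raise).
    """
    n = traj.n_frames
    max_lag = int(np.floor(n * max_lag_fraction))
    if max_lag < 2:
        raise ValueError(
            f"track of {n} frames yields only {max_lag} usable lag(s) at "
            f"max_lag_fraction={max_lag_fraction}; need >= 2"
        )
    pos = traj.positions
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=int)
    for i, k in enumerate(lags):
        disp = pos[k:] - pos[:-k]
        msd[i] = np.mean(np.sum(disp**2, axis=1))
        n_pairs[i] = n - k
    return MSDCurve(lags=lags * traj.dt, msd=msd, n_pairs=n_pairs)


def _window_indices(curve: MSDCurve, window: tuple[int, int]) -> np.ndarray:
    dt = curve.lags[0]  # first lag is 1 frame
    lag_index = np.rint(curve.lags / dt).astype(int)
    lo, hi = window
    return np.where((lag_index >= lo) & (lag_index <= hi))[0]


def fit_diffusion(curve: MSDCurve,
                  window: tuple[int, int] = (2, 10)) -> DiffusionFit:
    """Weighted least-squares fit of MSD = 4Dτ + b over a lag window.

    Weights are the pair counts per lag.  A negative slope is reported as a
    flagged negative D, never clipped to zero — clipping would bias ensemble
    averages of D upward.
    """
    idx = _window_indices(curve, window)
    if len(idx) < 3:
        raise ValueError(
            f"fit window {window} covers {len(idx)} lag(s); need >= 3"
        )
    tau = curve.lags[idx]
    y = curve.msd[idx]
    w = curve.n_pairs[idx].astype(float)
    X = np.column_stack([tau, np.ones_like(tau)])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    slope, intercept = coef
    yhat = X @ coef
    ss_res = np.sum(w * (y - yhat) ** 2)
    ybar = np.sum(w * y) / np.sum(w)
    ss_tot = np.sum(w * (y - ybar) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    D = slope / 4.0
    return DiffusionFit(D=float(D), intercept=float(intercept), r2=float(r2),
                        n_lags=len(idx), negative_D=D < 0)


def classify_simple_diffusion(curve: MSDCurve,
                              window: tuple[int, int] = (2, 10),
                              alpha_tol: float = 0.2,
                              r2_min: float = 0.9) -> SimpleDiffusionVerdict:
    """Anomalous-exponent test for simple diffusion.

    α is the slope of log MSD versus log τ over the window; the track is
    classified simple when |α − 1| ≤ alpha_tol and the log-log fit is good
    (r² ≥ r2_min).  Zero-MSD lags are excluded from the log fit; a curve
    with fewer than 4 positive lags in the window is not simple.
    """
    idx = _window_indices(curve, window)
    idx = idx[curve.msd[idx] > 0]
    if len(idx) < 4:
        return SimpleDiffusionVerdict(is_simple=False, alpha=float("nan"),
                                      r2=float("nan"))
    x = np.log(curve.lags[idx])
    y = np.log(curve.msd[idx])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - np.mean(y)) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    is_simple = bool(abs(slope - 1.0) <= alpha_tol and r2 >= r2_min)
    return SimpleDiffusionVerdict(is_simple=is_simple, alpha=float(slope),
                                  r2=float(r2))


def _bootstrap_sigma_D(traj: Trajectory, config: TrackingConfig,
                       rng: np.random.Generator) -> float:
    """Block bootstrap over displacement blocks; σ of the refitted D."""
    disp = np.diff(traj.positions, axis=0)
    block = config.boot_block
    n_blocks = len(disp) // block
    if n_blocks < 2:
        return float("nan")
    blocks = disp[: n_blocks * block].reshape(n_blocks, block, 2)
    n_pos = n_blocks * block + 1
    # only lags up to the fit window are refit; don't compute the full curve
    fraction = min(config.max_lag_fraction,
                   (config.fit_window[1] + 1) / n_pos)
    draws = []
    for _ in range(config.n_boot):
        pick = rng.integers(0, n_blocks, size=n_blocks)
        resampled = blocks[pick].reshape(-1, 2)
        pos = np.vstack([[0.0, 0.0], np.cumsum(resampled, axis=0)])
        times = traj.times[0] + np.arange(len(pos)) * traj.dt
        t = Trajectory(track_id=traj.track_id, times=times, positions=pos,
                       d_a=traj.d_a, phase=traj.phase)
        try:
            curve = compute_msd(t, fraction)
            draws.append(fit_diffusion(curve, config.fit_window).D)
        except ValueError:
            continue
    return float(np.std(draws, ddof=1)) if len(draws) > 1 else float("nan")


def estimate_observations(trajs, config: TrackingConfig | None = None):
    """Per-domain mobility estimates for the size–mobility analysis.

    Applies the simple-diffusion filter, fits D per surviving track, and
    attaches a block-bootstrap σ_D.  Returns ``(observations, exclusions)``
    where ``exclusions`` counts rejected tracks by reason.  Raises when no
    track survives, carrying the exclusion summary in the message.
    """
    if config is None:
        config = TrackingConfig()
    trajs = list(trajs)
    rng = np.random.default_rng(config.seed)
    observations: list[DomainObservation] = []
    exclusions = {"too_short": 0, "not_simple": 0, "negative_D": 0,
                  "missing_d_a": 0}
    for traj in trajs:
        if traj.d_a is None:
            exclusions["missing_d_a"] += 1
            continue
        try:
            curve = compute_msd(traj, config.max_lag_fraction)
            verdict = classify_simple_diffusion(
                curve, config.fit_window, config.alpha_tol, config.r2_min)
        except ValueError:
            exclusions["too_short"] += 1
            continue
        if not verdict.is_simple:
            exclusions["not_simple"] += 1
            continue
        fit = fit_diffusion(curve, config.fit_window)
        if fit.negative_D:
            exclusions["negative_D"] += 1
            continue
        sigma_D = _bootstrap_sigma_D(traj, config, rng)
        observations.append(DomainObservation(
            d_a=traj.d_a, D=fit.D,
            sigma_D=sigma_D if np.isfinite(sigma_D) else None,
            phase=traj.phase))
    if not observations:
        raise ValueError(
            f"no track passed the simple-diffusion filter; exclusions: "
            f"{exclusions} (of {len(trajs)} input tracks)"
        )
    return observations, exclusions
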