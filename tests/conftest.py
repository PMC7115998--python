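import numpy as np
import pytest

from nanodomain import HydroParams, Trajectory


@pytest.fixture
def lod_params():
    """Fitted parameters for tracked ordered domains (A μm²/s, β, δ μm)."""
    return HydroParams(A=0.76, beta=0.33, delta=0.57)


@pytest.fixture
def ldd_params():
    """Fitted parameters for tracked disordered domains."""
    return HydroParams(A=0.18, beta=0.20, delta=0.46)


def make_brownian_track(seed: int, D: float = 1.0, dt: float = 0.1,
                        n_frames: int = 500, sigma_loc: float = 0.0,
                        track_id: str | None = None, d_a: float | None = None,
                        phase: str = "unknown") -> Trajectory:
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_frames - 1, 2))
    pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    if sigma_loc > 0:
        pos = pos + rng.normal(0.0, sigma_loc, size=pos.shape)
    return Trajectory(track_id=track_id or f"bm_{seed}",
                      times=np.arange(n_frames) * dt, positions=pos,
                      d_a=d_a, phase=phase)
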