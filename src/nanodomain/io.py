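"""CSV / image I/O with schema validation for the pipeline's file formats.

Formats:

* trajectory CSV — ``track_id, frame, t_s, x_um, y_um, d_a_um, phase``
  (coordinates in μm, frame 0-based, origin arbitrary);
* observations CSV — ``d_a_um, D_um2_s, sigma_D, phase``;
* FCS CSV — ``tau_s, G`` with optional ``sigma_G``;
* images — single-channel grayscale TIFF or PNG per channel.

Schema violations raise ``SchemaError`` naming the offending column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fcs import FCSCurve
from .gsdfit import DomainObservation
from .tracking import Trajectory

__all__ = [
    "SchemaError",
    "read_trajectories",
    "write_trajectories",
    "read_observations",
    "write_observations",
    "read_fcs_curve",
    "write_fcs_curve",
    "read_image",
    "write_image",
]

TRAJECTORY_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]
OBSERVATION_COLUMNS = ["d_a_um", "D_um2_s"]


class SchemaError(ValueError):
    """A CSV is missing a required column or contains invalid rows."""


def _require_columns(frame: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(frame.columns)}"
        )


def read_trajectories(path) -> list[Trajectory]:
    frame = pd.read_csv(path)
    _require_columns(frame, TRAJECTORY_COLUMNS, path)
    if frame.empty:
        raise SchemaError(f"{path}: no trajectory rows")
    trajs = []
    for track_id, g in frame.groupby("track_id", sort=False):
        g = g.sort_values("frame")
        d_a = None
        if "d_a_um" in g.columns and g["d_a_um"].notna().any():
            d_a = float(g["d_a_um"].iloc[0])
        phase = str(g["phase"].iloc[0]) if "phase" in g.columns else "unknown"
        trajs.append(Trajectory(
            track_id=str(track_id),
            times=g["t_s"].to_numpy(float),
            positions=g[["x_um", "y_um"]].to_numpy(float),
            d_a=d_a, phase=phase))
    return trajs


def write_trajectories(trajs, path) -> None:
    rows = []
    for t in trajs:
        for frame_i, (time, (x, y)) in enumerate(zip(t.times, t.positions)):
            rows.append({"track_id": t.track_id, "frame": frame_i,
                         "t_s": time, "x_um": x, "y_um": y,
                         "d_a_um": t.d_a if t.d_a is not None else np.nan,
                         "phase": t.phase})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_observations(path) -> list[DomainObservation]:
    frame = pd.read_csv(path)
    _require_columns(frame, OBSERVATION_COLUMNS, path)
    if frame.empty:
        raise SchemaError(f"{path}: no observation rows")
    obs = []
    for i, row in frame.iterrows():
        sigma = row.get("sigma_D", np.nan)
        try:
            obs.append(DomainObservation(
                d_a=float(row["d_a_um"]), D=float(row["D_um2_s"]),
                sigma_D=None if pd.isna(sigma) else float(sigma),
                phase=str(row.get("phase", "unknown"))))
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from exc
    return obs


def write_observations(obs, path) -> None:
    pd.DataFrame([{
        "d_a_um": o.d_a, "D_um2_s": o.D,
        "sigma_D": o.sigma_D if o.sigma_D is not None else np.nan,
        "phase": o.phase,
    } for o in obs]).to_csv(path, index=False)


def read_fcs_curve(path) -> FCSCurve:
    frame = pd.read_csv(path)
    _require_columns(frame, ["tau_s", "G"], path)
    sigma = None
    if "sigma_G" in frame.columns and frame["sigma_G"].notna().all():
        sigma = frame["sigma_G"].to_numpy(float)
    return FCSCurve(taus=frame["tau_s"].to_numpy(float),
                    G=frame["G"].to_numpy(float), sigma_G=sigma)


def write_fcs_curve(curve: FCSCurve, path) -> None:
    data = {"tau_s": curve.taus, "G": curve.G}
    if curve.sigma_G is not None:
        data["sigma_G"] = curve.sigma_G
    pd.DataFrame(data).to_csv(path, index=False)


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    from PIL import Image

    return np.asarray(Image.open(path).convert("F"), dtype=float)


def write_image(image: np.ndarray, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    else:
        from PIL import Image

        arr = np.asarray(image, dtype=float)
        lo, hi = arr.min(), arr.max()
        scaled = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
        Image.fromarray((scaled * 65535).astype(np.uint16)).save(path)
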