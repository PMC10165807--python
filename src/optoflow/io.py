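"""File I/O: multi-page TIFF sequences, trace/table CSVs, schedule YAML."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import Episode, IlluminationSchedule, ImageSequence, RectRegion
from .flowfield import SpeedTrace, VelocityField
from .orientation import AngleTrace

__all__ = [
    "read_sequence",
    "write_sequence",
    "read_speed_trace",
    "write_speed_trace",
    "read_angle_trace",
    "write_angle_trace",
    "write_velocity_field",
    "read_velocity_field",
    "read_schedule",
    "write_schedule",
    "read_threshold_dataset",
    "write_threshold_dataset",
]

TRACE_COLUMNS = ["time_s", "value", "intensity_uW_mm2"]


class FormatError(ValueError):
    """A file does not match the expected on-disk schema."""


def write_sequence(seq: ImageSequence, path: str | os.PathLike) -> None:
    """Write frames as a multi-page TIFF; pixel size and frame interval go
    into the ImageJ-style metadata. Float frames are stored as float32
    unless already 16-bit."""
    frames = seq.frames
    if frames.dtype != np.uint16:
        frames = frames.astype(np.float32)
    tifffile.imwrite(
        path, frames, photometric="minisblack",
        metadata={"px_size_um": seq.px_size_um, "dt_s": seq.dt_s, "t0_s": seq.t0_s},
    )


def read_sequence(
    path: str | os.PathLike, px_size_um: float | None = None, dt_s: float | None = None
) -> ImageSequence:
    """Read a multi-page TIFF; metadata written by ``write_sequence`` is
    recovered, or can be overridden/supplied by the caller."""
    try:
        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    except (tifffile.TiffFileError, FileNotFoundError):
        raise
    except Exception as exc:  # malformed container
        raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise FormatError(f"{path}: expected a (T, H, W) stack, got shape {frames.shape}")
    px = px_size_um if px_size_um is not None else float(meta.get("px_size_um", 1.0))
    dt = dt_s if dt_s is not None else float(meta.get("dt_s", 1.0))
    return ImageSequence(np.asarray(frames, dtype=float), px_size_um=px, dt_s=dt,
                         t0_s=float(meta.get("t0_s", 0.0)))


def _write_trace(times, values, intensity, path) -> None:
    pd.DataFrame({
        "time_s": np.asarray(times, dtype=float),
        "value": np.asarray(values, dtype=float),
        "intensity_uW_mm2": np.asarray(intensity, dtype=float),
    }).to_csv(path, index=False, float_format="%.10g")


def _read_trace(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path}: empty trace")
    return df


def write_speed_trace(trace: SpeedTrace, path: str | os.PathLike) -> None:
    _write_trace(trace.times, trace.speed, trace.intensity, path)


def read_speed_trace(path: str | os.PathLike) -> SpeedTrace:
    df = _read_trace(path)
    return SpeedTrace(df["time_s"].to_numpy(), df["value"].to_numpy(),
                      df["intensity_uW_mm2"].to_numpy())


def write_angle_trace(trace: AngleTrace, path: str | os.PathLike) -> None:
    _write_trace(trace.times, trace.angle, trace.intensity, path)


def read_angle_trace(path: str | os.PathLike) -> AngleTrace:
    df = _read_trace(path)
    return AngleTrace(df["time_s"].to_numpy(), df["value"].to_numpy(),
                      df["intensity_uW_mm2"].to_numpy())


VFIELD_COLUMNS = ["x_um", "y_um", "vx_um_s", "vy_um_s", "valid"]


def write_velocity_field(field: VelocityField, path: str | os.PathLike) -> None:
    X, Y = np.meshgrid(field.x_um, field.y_um)
    pd.DataFrame({
        "x_um": X.ravel(), "y_um": Y.ravel(),
        "vx_um_s": field.vx.ravel(), "vy_um_s": field.vy.ravel(),
        "valid": field.valid.ravel().astype(int),
    }).to_csv(path, index=False, float_format="%.10g")


def read_velocity_field(path: str | os.PathLike, t_s: float = 0.0) -> VelocityField:
    df = pd.read_csv(path)
    missing = [c for c in VFIELD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    x = np.unique(df["x_um"].to_numpy())
    y = np.unique(df["y_um"].to_numpy())
    shape = (len(y), len(x))
    if len(df) != shape[0] * shape[1]:
        raise FormatError(f"{path}: irregular velocity grid")
    order = np.lexsort((df["x_um"], df["y_um"]))
    return VelocityField(
        x_um=x, y_um=y,
        vx=df["vx_um_s"].to_numpy()[order].reshape(shape),
        vy=df["vy_um_s"].to_numpy()[order].reshape(shape),
        valid=df["valid"].to_numpy()[order].reshape(shape).astype(bool),
        t_s=t_s,
    )


def write_schedule(schedule: IlluminationSchedule, path: str | os.PathLike) -> None:
    eps = []
    for ep in schedule.episodes:
        d = {"t_start": ep.t_start, "t_end": ep.t_end, "intensity": ep.intensity}
        if ep.region is not None:
            d["region"] = {"x0": ep.region.x0, "y0": ep.region.y0,
                           "length": ep.region.length, "width": ep.region.width}
        eps.append(d)
    Path(path).write_text(yaml.safe_dump({"episodes": eps}, sort_keys=False))


def read_schedule(path: str | os.PathLike) -> IlluminationSchedule:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "episodes" not in data:
        raise FormatError(f"{path}: missing 'episodes' key")
    episodes = []
    for d in data["episodes"]:
        region = None
        if d.get("region"):
            region = RectRegion(**d["region"])
        episodes.append(Episode(float(d["t_start"]), float(d["t_end"]),
                                float(d["intensity"]), region))
    return IlluminationSchedule(episodes)


THRESHOLD_COLUMNS = ["L_um", "W_um", "H_um", "I_threshold"]


def write_threshold_dataset(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def read_threshold_dataset(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in THRESHOLD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path}: empty dataset")
    return df
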