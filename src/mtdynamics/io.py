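"""File I/O: CSV traces and events, TIFF movies/kymographs, YAML config
and run manifests.

All CSV outputs carry a header row with units in the column names; every
manifest records the configuration, seed, and SHA-256 of each input so a
run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .trace import LengthTrace
from .kymo import Kymograph

__all__ = [
    "AnalysisConfig",
    "write_trace_csv",
    "read_trace_csv",
    "write_events_csv",
    "write_kymograph",
    "read_kymograph",
    "write_movie_tiff",
    "read_movie_tiff",
    "read_growth_csv",
    "write_manifest",
]


@dataclass
class AnalysisConfig:
    """All pipeline thresholds in one place.

    Defaults: 1,750 subunits per μm (14-protofilament lattice), 150 nm·s⁻¹
    catastrophe slope threshold over 5-point regression windows, the
    three-rule in vivo criterion (>=3 points, >=0.5 μm, R² >= 0.80), a 10-s
    pre-washout regression window, and a 4-pixel crop half-width.
    """

    subunits_per_um: float = 1750.0
    catastrophe_slope_threshold_nm_s: float = 150.0
    regression_window: int = 5
    invivo_min_points: int = 3
    invivo_min_delta_um: float = 0.5
    invivo_min_r2: float = 0.80
    prewashout_window_s: float = 10.0
    crop_halfwidth_px: int = 4
    pixel_size_nm: float = 65.0
    frame_interval_s: float = 3.0
    threshold_method: str = "otsu"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "subunits_per_um",
            "catastrophe_slope_threshold_nm_s",
            "regression_window",
            "invivo_min_points",
            "invivo_min_delta_um",
            "invivo_min_r2",
            "prewashout_window_s",
            "crop_halfwidth_px",
            "pixel_size_nm",
            "frame_interval_s",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.threshold_method not in ("otsu", "fixed", "background"):
            raise ValueError("threshold_method must be otsu|fixed|background")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def write_trace_csv(trace: LengthTrace, path) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(len(trace)),
            "time_s": trace.times_s,
            "length_um": trace.lengths_um,
        }
    )
    if trace.states is not None:
        df["state"] = trace.states
    if trace.flags is not None:
        df["flag"] = trace.flags.astype(int)
    df.to_csv(path, index=False)


def read_trace_csv(path, frame_interval_s: Optional[float] = None) -> LengthTrace:
    """Read a trace CSV (columns time_s, length_um, optional state/flag).

    The frame interval is read from the time stamps unless given.
    """
    df = pd.read_csv(path)
    times = df["time_s"].to_numpy(dtype=float)
    if frame_interval_s is None:
        if times.size < 2:
            raise ValueError("cannot infer frame interval from a single sample")
        frame_interval_s = float(np.median(np.diff(times)))
    return LengthTrace(
        times_s=times,
        lengths_um=df["length_um"].to_numpy(dtype=float),
        frame_interval_s=frame_interval_s,
        states=df["state"].to_numpy() if "state" in df else None,
        flags=df["flag"].to_numpy(dtype=bool) if "flag" in df else None,
    )


def write_events_csv(events: Sequence, frame_interval_s: float, path) -> None:
    rows = []
    for k, ev in enumerate(events):
        rows.append(
            {
                "event": k,
                "kind": ev.kind,
                "start_idx": ev.start_idx,
                "end_idx": ev.end_idx,
                "start_s": ev.start_idx * frame_interval_s,
                "end_s": ev.end_idx * frame_interval_s,
                "delta_length_um": ev.delta_length_um,
                "rate_um_min": ev.rate_um_min,
                "r2": ev.r_squared,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_kymograph(kymo: Kymograph, path) -> None:
    """Write a kymograph as single-page TIFF (.tif) or CSV matrix (.csv)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            kymo.intensity.astype(np.float32),
            metadata={
                "pixel_size_nm": kymo.pixel_size_nm,
                "frame_interval_s": kymo.frame_interval_s,
                "seed_span_px": list(kymo.seed_span_px),
            },
        )
    else:
        np.savetxt(path, kymo.intensity, delimiter=",")


def read_kymograph(
    path, pixel_size_nm: float, frame_interval_s: float, seed_span_px=(0, 0)
) -> Kymograph:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        mat = tifffile.imread(path).astype(float)
    else:
        mat = np.loadtxt(path, delimiter=",")
    return Kymograph(
        intensity=mat,
        pixel_size_nm=pixel_size_nm,
        frame_interval_s=frame_interval_s,
        seed_span_px=tuple(seed_span_px),
    )


def write_movie_tiff(channels: dict, path) -> None:
    """Write a two-channel movie as a (T, C, H, W) 16-bit multi-page TIFF."""
    names = sorted(channels)
    stack = np.stack([channels[n] for n in names], axis=1)
    peak = stack.max()
    scale = 1.0 if peak <= 0 else min(1.0, 65535.0 / peak)
    tifffile.imwrite(
        path,
        np.clip(stack * scale, 0, 65535).astype(np.uint16),
        metadata={"axes": "TCYX", "channels": names, "scale": scale},
    )


def read_movie_tiff(path) -> dict:
    """Read a (T, C, H, W) movie written by :func:`write_movie_tiff`."""
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray().astype(float)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if stack.ndim == 3:
        stack = stack[:, None, :, :]
    names = meta.get("channels", [f"ch{i}" for i in range(stack.shape[1])])
    return {n: stack[:, i] for i, n in enumerate(names)}


def read_growth_csv(path, time_col: str = "time_min"):
    """Read a plate-reader CSV in wide format (time + one column per well).

    Returns a list of :class:`~mtdynamics.simulate.GrowthCurve`.
    """
    from .simulate import GrowthCurve

    df = pd.read_csv(path)
    if time_col not in df.columns:
        raise ValueError(f"missing time column {time_col!r}")
    t = df[time_col].to_numpy(dtype=float)
    return [
        GrowthCurve(times_min=t, od600=df[c].to_numpy(dtype=float), well=c)
        for c in df.columns
        if c != time_col
    ]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: AnalysisConfig, inputs: Sequence = (), **extra) -> None:
    """Run manifest: config echo, package version, seed, input hashes."""
    from . import __version__

    manifest = {
        "mtdynamics_version": __version__,
        "config": asdict(config),
        "rng_seed": config.rng_seed,
        "inputs": {str(p): _sha256(p) for p in inputs},
        **extra,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
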