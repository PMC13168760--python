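"""File round-trips: image stacks, trace CSVs, histograms, configs.

Conventions: images are TIFF (16-bit by default) or PNG; tabular artifacts
are CSV with explicit units in the header names; scalar records are JSON.
Every physical quantity in a config carries its unit in the key name
(``pixel_size_um``, ``frame_rate_hz``, ``k_un_per_um``); unknown keys are
rejected rather than ignored.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .contractility import ForceTrace
from .orientation import OrientationDistribution
from .tracking import DeflectionTrace, ImageSequence

__all__ = [
    "save_image_sequence",
    "load_image_sequence",
    "save_trace_csv",
    "load_trace_csv",
    "save_force_csv",
    "load_force_csv",
    "save_histogram_csv",
    "save_oi_json",
    "load_config",
    "ConfigError",
]

_METADATA_NAME = "metadata.yaml"
_METADATA_KEYS = {"pixel_size_um", "frame_rate_hz"}


class ConfigError(ValueError):
    """Malformed or incomplete configuration."""


def _to_uint16(frame: np.ndarray) -> np.ndarray:
    lo, hi = float(frame.min()), float(frame.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 0.0
    return ((frame - lo) * scale).astype(np.uint16)


def save_image_sequence(seq: ImageSequence, directory: str | Path) -> Path:
    """Write frames as 16-bit TIFFs plus a metadata sidecar; returns the dir.

    Frames are scaled jointly so relative intensities survive quantization.
    """
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    lo, hi = float(seq.frames.min()), float(seq.frames.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 0.0
    for i, frame in enumerate(seq.frames):
        tifffile.imwrite(
            directory / "images" / f"frame_{i:04d}.tif",
            ((frame - lo) * scale).astype(np.uint16),
        )
    with open(directory / _METADATA_NAME, "w") as fh:
        yaml.safe_dump(
            {
                "pixel_size_um": float(seq.pixel_size_um),
                "frame_rate_hz": float(seq.frame_rate_hz),
            },
            fh,
        )
    return directory


def load_image_sequence(directory: str | Path) -> ImageSequence:
    """Read a frame directory written by :func:`save_image_sequence`.

    Accepts any directory holding ``images/*.tif`` (or ``*.png``) plus a
    ``metadata.yaml`` sidecar with ``pixel_size_um`` and ``frame_rate_hz``.
    """
    directory = Path(directory)
    meta_path = directory / _METADATA_NAME
    if not meta_path.exists():
        raise ConfigError(f"missing {_METADATA_NAME} sidecar in {directory}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh) or {}
    unknown = set(meta) - _METADATA_KEYS
    if unknown:
        raise ConfigError(f"unknown metadata keys: {sorted(unknown)}")
    missing = _METADATA_KEYS - set(meta)
    if missing:
        raise ConfigError(f"metadata missing required keys: {sorted(missing)}")

    image_dir = directory / "images" if (directory / "images").is_dir() else directory
    paths = sorted(
        p for p in image_dir.iterdir() if p.suffix.lower() in {".tif", ".tiff", ".png"}
    )
    if not paths:
        raise ConfigError(f"no frames found under {image_dir}")
    frames = []
    for p in paths:
        if p.suffix.lower() == ".png":
            import imageio.v3 as iio

            frames.append(np.asarray(iio.imread(p), dtype=float))
        else:
            frames.append(np.asarray(tifffile.imread(p), dtype=float))
    return ImageSequence(
        frames=np.stack(frames),
        pixel_size_um=float(meta["pixel_size_um"]),
        frame_rate_hz=float(meta["frame_rate_hz"]),
    )


def save_trace_csv(trace: DeflectionTrace, path: str | Path) -> Path:
    path = Path(path)
    trace.to_frame().to_csv(path, index=False, float_format="%.6g")
    return path


def load_trace_csv(path: str | Path) -> DeflectionTrace:
    df = pd.read_csv(path)
    return DeflectionTrace(
        time_s=df["time_s"].to_numpy(),
        left_deflection_um=df["left_defl_um"].to_numpy(),
        right_deflection_um=df["right_defl_um"].to_numpy(),
        interpillar_distance_um=df["distance_um"].to_numpy(),
    )


def save_force_csv(force: ForceTrace, path: str | Path) -> Path:
    path = Path(path)
    force.to_frame().to_csv(path, index=False, float_format="%.6g")
    return path


def load_force_csv(path: str | Path) -> ForceTrace:
    df = pd.read_csv(path)
    return ForceTrace(
        time_s=df["time_s"].to_numpy(),
        left_force_un=df["left_force_uN"].to_numpy(),
        right_force_un=df["right_force_uN"].to_numpy(),
    )


def save_histogram_csv(dist: OrientationDistribution, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"angle_deg": dist.angles_deg, "weight": dist.weights}).to_csv(
        path, index=False, float_format="%.6g"
    )
    return path


def save_oi_json(
    oi: float, dist: OrientationDistribution, path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(
            {
                "OI": round(float(oi), 6),
                "n_bins": dist.n_bins,
                "bin_width_deg": dist.bin_width_deg,
                "degenerate": dist.degenerate,
            },
            fh,
            indent=2,
        )
    return path


_CONFIG_KEYS = {
    "geometry": {
        "semi_major_a_um",
        "semi_minor_b_um",
        "height_h_um",
        "youngs_modulus_mpa",
        "poisson_nu",
    },
    "calibration": {"k_un_per_um", "load_height_um"},
    "protocol": {"pulse_width_ms", "amplitude_v", "electrode_gap_mm", "epochs"},
    "analysis": {"windows_s", "channel"},
    "run": {"seed", "output_dir"},
}


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML run configuration.

    Top-level sections and their keys are checked against the documented
    schema; any unknown key raises :class:`ConfigError` naming it, so typos
    cannot silently fall back to defaults.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    unknown_sections = set(cfg) - set(_CONFIG_KEYS)
    if unknown_sections:
        raise ConfigError(f"unknown config section(s): {sorted(unknown_sections)}")
    for section, keys in _CONFIG_KEYS.items():
        if section in cfg:
            if not isinstance(cfg[section], dict):
                raise ConfigError(f"config section {section!r} must be a mapping")
            unknown = set(cfg[section]) - keys
            if unknown:
                raise ConfigError(
                    f"unknown key(s) in section {section!r}: {sorted(unknown)}"
                )
    return cfg
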