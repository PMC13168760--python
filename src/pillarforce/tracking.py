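"""Pillar centroid detection and deflection/compaction trace extraction.

The contractility readout is optical: each video frame shows the two
force-sensing pillars, whose bright elliptical tips are detected, localized
to sub-pixel precision with intensity-weighted centroids, and tracked
across frames.  Two derived series matter downstream:

* interpillar distance (um) — the Euclidean distance between the two
  centroids; its decline over days of culture reports compaction-driven
  tissue shortening;
* per-pillar deflection (um) — signed displacement of each pillar along
  the interpillar axis relative to the first frame, positive toward the
  opposite pillar (contraction positive).  The first frame defines zero:
  pre-tension present before the recording began is not recoverable from
  the video, so displacement-based forces underestimate total force when
  stimulation-evoked deflection is small next to pre-deflection.

Detection is deterministic: global Otsu threshold, connected components,
area filter, intensity-weighted centroids, ordered left-to-right.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "ImageSequence",
    "DeflectionTrace",
    "DetectionError",
    "TrackingError",
    "detect_pillar_centroids",
    "interpillar_distance",
    "track_sequence",
    "compaction_metrics",
]


class DetectionError(RuntimeError):
    """Pillar detection found the wrong number of candidate blobs."""


class TrackingError(RuntimeError):
    """Frame-to-frame identity assignment failed (likely pillar swap)."""


@dataclass(frozen=True)
class ImageSequence:
    """Calibrated grayscale frame stack.

    ``frames`` is (T, H, W); ``timestamps_s`` default to ``arange(T)/rate``.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_rate_hz: float
    timestamps_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if self.pixel_size_um <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("pixel size and frame rate must be positive")
        object.__setattr__(self, "frames", frames)
        ts = self.timestamps_s
        if ts is None:
            ts = np.arange(frames.shape[0]) / self.frame_rate_hz
        ts = np.asarray(ts, dtype=float)
        if ts.shape != (frames.shape[0],):
            raise ValueError("timestamps must have one entry per frame")
        object.__setattr__(self, "timestamps_s", ts)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass(frozen=True)
class DeflectionTrace:
    """Per-frame pillar deflections and interpillar distance, calibrated."""

    time_s: np.ndarray
    left_deflection_um: np.ndarray
    right_deflection_um: np.ndarray
    interpillar_distance_um: np.ndarray

    def __post_init__(self) -> None:
        arrays = {
            name: np.asarray(getattr(self, name), dtype=float)
            for name in (
                "time_s",
                "left_deflection_um",
                "right_deflection_um",
                "interpillar_distance_um",
            )
        }
        n = arrays["time_s"].size
        for name, arr in arrays.items():
            if arr.ndim != 1 or arr.size != n:
                raise ValueError("all trace arrays must be 1-D and equal length")
            object.__setattr__(self, name, arr)
        if np.any(arrays["interpillar_distance_um"] <= 0):
            raise ValueError("interpillar distance must be positive everywhere")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "left_defl_um": self.left_deflection_um,
                "right_defl_um": self.right_deflection_um,
                "distance_um": self.interpillar_distance_um,
            }
        )


def detect_pillar_centroids(
    frame: np.ndarray,
    expected_count: int = 2,
    min_area_px: int = 20,
    frame_index: int | None = None,
) -> list[tuple[float, float]]:
    """Sub-pixel pillar centroids ``(x, y)`` in pixels, ordered left to right.

    Global Otsu threshold -> connected components -> area filter -> the
    ``expected_count`` largest blobs must be exactly the blobs that survive
    the filter, else a :class:`DetectionError` naming the frame is raised.
    Centroids are intensity-weighted over each blob (pixel centers,
    0-based), so localization is sub-pixel on smooth blobs.
    """
    frame = np.asarray(frame, dtype=float)
    if float(np.ptp(frame)) == 0.0:
        raise DetectionError(
            f"frame {frame_index if frame_index is not None else '?'} is constant"
        )
    mask = frame > threshold_otsu(frame)
    labels = label(mask)
    props = [p for p in regionprops(labels, intensity_image=frame) if p.area >= min_area_px]
    if len(props) != expected_count:
        raise DetectionError(
            f"expected {expected_count} pillars, found {len(props)} blobs "
            f"in frame {frame_index if frame_index is not None else '?'}"
        )
    centroids = []
    for p in props:
        row, col = p.centroid_weighted
        centroids.append((float(col), float(row)))
    centroids.sort(key=lambda c: c[0])
    return centroids


def interpillar_distance(
    centroids: "list[tuple[float, float]]", pixel_size_um: float
) -> float:
    """Euclidean center-to-center distance between the two pillars, in um."""
    if len(centroids) != 2:
        raise ValueError("exactly two centroids required")
    (x0, y0), (x1, y1) = centroids
    d_px = float(np.hypot(x1 - x0, y1 - y0))
    if d_px == 0.0:
        warnings.warn("coincident centroids: interpillar distance is 0", stacklevel=2)
    return d_px * pixel_size_um


def track_sequence(
    seq: ImageSequence, expected_count: int = 2, min_area_px: int = 20
) -> DeflectionTrace:
    """Track both pillars through the sequence and calibrate displacements.

    Frame 0 is the zero-deflection reference.  Identities are kept by
    nearest-neighbor assignment against the previous frame; an assignment
    step larger than half the current interpillar distance indicates a
    swap or a detection jump and raises :class:`TrackingError`.
    """
    ref = np.array(
        detect_pillar_centroids(
            seq.frames[0], expected_count, min_area_px, frame_index=0
        )
    )
    axis = ref[1] - ref[0]
    axis = axis / np.linalg.norm(axis)

    positions = np.empty((seq.n_frames, 2, 2))
    positions[0] = ref
    prev = ref
    for t in range(1, seq.n_frames):
        detected = np.array(
            detect_pillar_centroids(
                seq.frames[t], expected_count, min_area_px, frame_index=t
            )
        )
        # nearest-neighbor identity assignment against previous frame
        d = np.linalg.norm(prev[:, None, :] - detected[None, :, :], axis=2)
        order = np.argmin(d, axis=1)
        if order[0] == order[1]:
            raise TrackingError(f"ambiguous pillar assignment in frame {t}")
        step = d[np.arange(2), order]
        gap = np.linalg.norm(detected[1] - detected[0])
        if np.any(step > gap / 2.0):
            raise TrackingError(
                f"assignment jump {step.max():.1f} px exceeds half the "
                f"interpillar distance in frame {t} (likely identity swap)"
            )
        positions[t] = detected[order]
        prev = positions[t]

    disp = positions - ref[None, :, :]
    # contraction positive: left pillar moving along +axis, right along -axis
    left = disp[:, 0, :] @ axis
    right = -(disp[:, 1, :] @ axis)
    dist_px = np.linalg.norm(positions[:, 1, :] - positions[:, 0, :], axis=1)
    return DeflectionTrace(
        time_s=seq.timestamps_s,
        left_deflection_um=left * seq.pixel_size_um,
        right_deflection_um=right * seq.pixel_size_um,
        interpillar_distance_um=dist_px * seq.pixel_size_um,
    )


def compaction_metrics(
    trace: DeflectionTrace, windows: "list[tuple[float, float]]"
) -> pd.DataFrame:
    """Interpillar-distance reduction over each ``(t0, t1)`` window, in um.

    Reduction is ``distance(t0) - distance(t1)``; positive values mean the
    tissue shortened.  Distances are linearly interpolated between samples.
    Windows outside the recorded time span raise ``ValueError``.
    """
    t = trace.time_s
    d = trace.interpillar_distance_um
    rows = []
    for t0, t1 in windows:
        if t0 < t[0] or t1 > t[-1] or t1 <= t0:
            raise ValueError(
                f"window ({t0}, {t1}) outside trace span [{t[0]}, {t[-1]}]"
            )
        d0 = float(np.interp(t0, t, d))
        d1 = float(np.interp(t1, t, d))
        rows.append({"t0_s": t0, "t1_s": t1, "reduction_um": d0 - d1})
    return pd.DataFrame(rows)
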