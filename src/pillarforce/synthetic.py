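"""Synthetic microscopy data with ground truth for pipeline benchmarking.

No public raw recordings exist for this class of two-pillar muscle
platform, so every pipeline input can be generated here with known ground
truth: bright-field-like two-pillar frames whose centroids follow a
programmed compaction drift plus contraction oscillation; fluorescence-like
fiber textures with a prescribed angular distribution; and cohorts of
tissues with condition-dependent effect multipliers (spacer/no-spacer,
drug dose ladders).  Every artifact carries a :class:`GroundTruth` sidecar
and is bitwise reproducible from its seed.

Default study conditions mirror the platform: 2.6 mm pillar spacing,
elliptical pillar tips (a = 300 um across, b = 200 um along the axis),
10 um/px at low magnification, bright-field imaging every other day for
compaction, and twitch/tetanus stimulation at 1 and 90 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import line_aa

from .contractility import ForceTrace, StimulusProtocol, TwitchKernel, simulate_contraction
from .orientation import FiberImage
from .tracking import ImageSequence

__all__ = [
    "GroundTruth",
    "CohortCondition",
    "generate_pillar_sequence",
    "generate_fiber_image",
    "generate_cohort",
    "stripe_image",
    "DEX_SCENARIO",
    "TES_SCENARIO",
    "SPACER_SCENARIO",
    "DEFAULT_SPAN_UM",
    "DEFAULT_PIXEL_SIZE_UM",
]

DEFAULT_SPAN_UM = 2600.0
DEFAULT_PIXEL_SIZE_UM = 10.0
DEFAULT_SEMI_MAJOR_UM = 300.0  # across the interpillar axis
DEFAULT_SEMI_MINOR_UM = 200.0  # along the interpillar axis (bending direction)


@dataclass(frozen=True)
class GroundTruth:
    """Programmed truth attached to every generated artifact."""

    seed: int | None
    centroid_trajectories_px: np.ndarray | None = None
    contraction_waveform_um: np.ndarray | None = None
    compaction_profile_um: np.ndarray | None = None
    fiber_modal_angle_deg: float | None = None
    fiber_concentration: float | None = None
    dose_multipliers: dict | None = None
    params: dict = field(default_factory=dict)


def _ellipse_sprite(X, Y, cx, cy, rx, ry, edge_px=1.5):
    """Smooth-edged unit ellipse; soft edge keeps the centroid sub-pixel."""
    d = np.sqrt(((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2)
    width = edge_px / min(rx, ry)
    return 1.0 / (1.0 + np.exp((d - 1.0) / max(width, 1e-6)))


def generate_pillar_sequence(
    n_frames: int = 8,
    frame_rate_hz: float = 0.5,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    span_um: float = DEFAULT_SPAN_UM,
    semi_major_um: float = DEFAULT_SEMI_MAJOR_UM,
    semi_minor_um: float = DEFAULT_SEMI_MINOR_UM,
    compaction_total_um: float = 0.0,
    compaction_profile_um: np.ndarray | None = None,
    contraction_amplitude_um: float = 0.0,
    contraction_frequency_hz: float = 1.0,
    contraction_waveform_um: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    margin_px: int = 40,
    seed: int | None = None,
) -> tuple[ImageSequence, GroundTruth]:
    """Render a two-pillar bright-field-like sequence with known trajectories.

    The two pillar tips start ``span_um`` apart and move symmetrically
    inward following a compaction profile (linear ramp totalling
    ``compaction_total_um`` unless an explicit per-frame profile is given,
    in um of interpillar-distance reduction) plus a per-pillar contraction
    oscillation (sinusoid of ``contraction_amplitude_um`` unless an
    explicit waveform is given, in um of inward tip displacement).
    Gaussian pixel noise of ``noise_sigma`` (fraction of the pillar/background
    contrast) is added.  Raises if any trajectory leaves the frame.
    """
    t = np.arange(n_frames) / frame_rate_hz
    if compaction_profile_um is None:
        compaction = (
            compaction_total_um * np.linspace(0.0, 1.0, n_frames)
            if n_frames > 1
            else np.zeros(1)
        )
    else:
        compaction = np.asarray(compaction_profile_um, dtype=float)
        if compaction.shape != (n_frames,):
            raise ValueError("compaction profile must have one value per frame")
    if contraction_waveform_um is None:
        contraction = contraction_amplitude_um * 0.5 * (
            1.0 - np.cos(2.0 * np.pi * contraction_frequency_hz * t)
        )
    else:
        contraction = np.asarray(contraction_waveform_um, dtype=float)
        if contraction.shape != (n_frames,):
            raise ValueError("contraction waveform must have one value per frame")

    rx = semi_minor_um / pixel_size_um  # along x: bending-direction semi-axis
    ry = semi_major_um / pixel_size_um
    span_px = span_um / pixel_size_um
    width = int(np.ceil(span_px + 2 * (margin_px + rx)))
    height = int(np.ceil(2 * (ry + margin_px)))
    cy = height / 2.0
    x_left0 = margin_px + rx
    x_right0 = x_left0 + span_px

    # per-frame centroid x positions: symmetric compaction + contraction
    inward_px = (compaction / 2.0 + contraction) / pixel_size_um
    xl = x_left0 + inward_px
    xr = x_right0 - inward_px
    if np.any(xl - rx < 0) or np.any(xr + rx > width) or np.any(xr - xl <= 0):
        raise ValueError("programmed trajectory leaves the frame or pillars collide")

    rng = np.random.default_rng(seed)
    Y, X = np.mgrid[0:height, 0:width].astype(float)
    background = 0.15 + 0.03 * gaussian_filter(
        rng.standard_normal((height, width)), sigma=6.0
    )
    frames = np.empty((n_frames, height, width), dtype=float)
    for i in range(n_frames):
        img = background.copy()
        img += 0.85 * _ellipse_sprite(X, Y, xl[i], cy, rx, ry)
        img += 0.85 * _ellipse_sprite(X, Y, xr[i], cy, rx, ry)
        if noise_sigma > 0:
            img += noise_sigma * rng.standard_normal(img.shape)
        frames[i] = img

    trajectories = np.stack(
        [np.column_stack([xl, np.full(n_frames, cy)]),
         np.column_stack([xr, np.full(n_frames, cy)])],
        axis=1,
    )  # (T, 2 pillars, xy)
    seq = ImageSequence(
        frames=frames,
        pixel_size_um=pixel_size_um,
        frame_rate_hz=frame_rate_hz,
        timestamps_s=t,
    )
    truth = GroundTruth(
        seed=seed,
        centroid_trajectories_px=trajectories,
        contraction_waveform_um=contraction,
        compaction_profile_um=compaction,
        params={
            "span_um": span_um,
            "pixel_size_um": pixel_size_um,
            "compaction_total_um": float(compaction[-1] - compaction[0]),
            "contraction_amplitude_um": float(contraction_amplitude_um),
            "noise_sigma": noise_sigma,
        },
    )
    return seq, truth


def _sample_axial_angles(
    rng: np.random.Generator, n: int, modal_angle_deg: float | None, concentration: float
) -> np.ndarray:
    """Axial (180-degree periodic) angles in degrees on [-90, 90)."""
    if modal_angle_deg is None or concentration == 0.0:
        return rng.uniform(-90.0, 90.0, n)
    # double-angle von Mises: standard construction for axial data
    doubled = rng.vonmises(np.deg2rad(2.0 * modal_angle_deg), concentration, n)
    theta = np.rad2deg(doubled) / 2.0
    return (theta + 90.0) % 180.0 - 90.0


def generate_fiber_image(
    modal_angle_deg: float | None = 0.0,
    concentration: float = 10.0,
    size: int = 256,
    snr: float = 10.0,
    n_lines: int = 400,
    pixel_size_um: float = 0.5,
    seed: int | None = None,
) -> tuple[FiberImage, GroundTruth]:
    """Render a fiber-like texture with a prescribed angular distribution.

    Anti-aliased line segments are drawn at angles sampled from an axial
    von Mises distribution (mode ``modal_angle_deg``, ``concentration`` =
    kappa of the doubled angle); ``modal_angle_deg=None`` or
    ``concentration=0`` gives an isotropic texture.  Angles follow the
    package convention: 0 deg horizontal, counterclockwise positive.
    Gaussian noise is added to reach the requested signal-to-noise ratio
    (signal SD / noise SD).  ``n_lines = 0`` yields a degenerate constant
    image (flagged downstream by the histogram estimator).
    """
    if concentration < 0:
        raise ValueError("concentration must be nonnegative")
    rng = np.random.default_rng(seed)
    canvas = np.zeros((size, size), dtype=float)
    angles = _sample_axial_angles(rng, n_lines, modal_angle_deg, concentration)
    half_len = size / 3.0
    for theta in angles:
        cx = rng.uniform(0, size)
        cy = rng.uniform(0, size)
        dx = half_len * np.cos(np.deg2rad(theta))
        drow = -half_len * np.sin(np.deg2rad(theta))  # row grows downward
        r0 = int(np.clip(round(cy - drow), 0, size - 1))
        c0 = int(np.clip(round(cx - dx), 0, size - 1))
        r1 = int(np.clip(round(cy + drow), 0, size - 1))
        c1 = int(np.clip(round(cx + dx), 0, size - 1))
        rr, cc, val = line_aa(r0, c0, r1, c1)
        canvas[rr, cc] += val
    canvas = gaussian_filter(canvas, sigma=0.6)
    signal_sd = float(canvas.std())
    if signal_sd > 0 and np.isfinite(snr) and snr > 0:
        canvas = canvas + rng.normal(0.0, signal_sd / snr, canvas.shape)
    image = FiberImage(intensity=canvas, pixel_size_um=pixel_size_um)
    truth = GroundTruth(
        seed=seed,
        fiber_modal_angle_deg=modal_angle_deg,
        fiber_concentration=concentration,
        params={"size": size, "snr": snr, "n_lines": n_lines},
    )
    return image, truth


def stripe_image(
    angle_deg: float, size: int = 256, period_px: float = 12.0, pixel_size_um: float = 0.5
) -> FiberImage:
    """Deterministic sinusoidal stripes running along ``angle_deg``.

    A pure plane wave whose crests are lines at the requested angle — the
    sharpest possible orientation fixture.
    """
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    x, y = cols, -rows  # y up, CCW-positive angles
    # wave vector perpendicular to the stripe direction
    kx = -np.sin(np.deg2rad(angle_deg)) / period_px
    ky = np.cos(np.deg2rad(angle_deg)) / period_px
    return FiberImage(
        intensity=np.sin(2.0 * np.pi * (kx * x + ky * y)),
        pixel_size_um=pixel_size_um,
    )


@dataclass(frozen=True)
class CohortCondition:
    """Programmed effect for one experimental condition."""

    force_multiplier: float = 1.0
    compaction_um: float = 0.0
    dose: float | None = None

    def __post_init__(self) -> None:
        if self.force_multiplier < 0:
            raise ValueError("force multiplier must be nonnegative")


#: Glucocorticoid atrophy scenario: dose-dependent force decrease
#: (multipliers are free parameters with the reported sign, not measured values).
DEX_SCENARIO: dict[str, CohortCondition] = {
    "vehicle": CohortCondition(1.0, dose=0.0),
    "DEX 0.01 mM": CohortCondition(0.9, dose=0.01),
    "DEX 0.1 mM": CohortCondition(0.7, dose=0.1),
    "DEX 1.0 mM": CohortCondition(0.4, dose=1.0),
}

#: Anabolic scenario: dose-dependent force increase.
TES_SCENARIO: dict[str, CohortCondition] = {
    "vehicle": CohortCondition(1.0, dose=0.0),
    "TES 0.01 uM": CohortCondition(1.05, dose=0.01),
    "TES 0.1 uM": CohortCondition(1.2, dose=0.1),
    "TES 1.0 uM": CohortCondition(1.35, dose=1.0),
}

#: Fixed-length boundary condition: the spacer holds the interpillar
#: distance (zero compaction) and matured tissues contract harder.
SPACER_SCENARIO: dict[str, CohortCondition] = {
    "spacer+": CohortCondition(1.5, compaction_um=0.0),
    "spacer-": CohortCondition(1.0, compaction_um=400.0),
}


def generate_cohort(
    conditions: Mapping[str, CohortCondition | Mapping],
    n_per_group: int = 5,
    seed: int | None = 0,
    base_kernel: TwitchKernel = TwitchKernel(),
    protocol: StimulusProtocol | None = None,
    noise_sigma_un: float = 0.05,
    labels: "list[str] | None" = None,
) -> dict:
    """Simulate a cohort of tissues with condition-dependent effects.

    Each tissue gets a per-pillar force trace from the twitch-kernel model
    with the condition's programmed amplitude multiplier, plus mild
    tissue-to-tissue amplitude variability (5% CV).  Returns a bundle with
    ``traces`` (tissue id -> ForceTrace), ``manifest`` (one row per
    tissue), ``protocol`` and ``ground_truth``.  ``labels`` restricts or
    re-orders the generated conditions; an unknown label raises.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be at least 1")
    conds = {
        name: c if isinstance(c, CohortCondition) else CohortCondition(**c)
        for name, c in conditions.items()
    }
    if labels is None:
        labels = list(conds)
    unknown = [l for l in labels if l not in conds]
    if unknown:
        raise ValueError(f"unknown condition label(s): {unknown}")
    if protocol is None:
        # default assay: 1 Hz twitch epoch then a 90 Hz tetanic epoch
        protocol = StimulusProtocol(epochs=((2.0, 8.0, 1.0), (10.0, 13.0, 90.0)))

    root = np.random.SeedSequence(seed)
    traces: dict[str, ForceTrace] = {}
    rows = []
    for label_idx, name in enumerate(labels):
        cond = conds[name]
        for i in range(n_per_group):
            child = root.spawn(1)[0]
            tissue_rng = np.random.default_rng(child)
            tissue_seed = int(tissue_rng.integers(0, 2**31 - 1))
            variability = 1.0 + 0.05 * tissue_rng.standard_normal()
            amplitude = max(
                base_kernel.amplitude_un * cond.force_multiplier * variability, 0.0
            )
            kernel = TwitchKernel(
                amplitude_un=amplitude,
                tau_rise_s=base_kernel.tau_rise_s,
                tau_decay_s=base_kernel.tau_decay_s,
            )
            tissue_id = f"{name}/tissue{i:02d}"
            traces[tissue_id] = simulate_contraction(
                protocol,
                kernel=kernel,
                noise_sigma_un=noise_sigma_un,
                seed=tissue_seed,
            )
            rows.append(
                {
                    "tissue_id": tissue_id,
                    "condition": name,
                    "dose": cond.dose,
                    "programmed_amplitude_un": amplitude,
                    "programmed_compaction_um": cond.compaction_um,
                    "seed": tissue_seed,
                }
            )
    manifest = pd.DataFrame(rows)
    truth = GroundTruth(
        seed=seed,
        dose_multipliers={n: conds[n].force_multiplier for n in labels},
        params={"n_per_group": n_per_group, "noise_sigma_un": noise_sigma_un},
    )
    return {
        "traces": traces,
        "manifest": manifest,
        "protocol": protocol,
        "ground_truth": truth,
    }
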