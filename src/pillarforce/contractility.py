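"""Force traces and twitch/tetanus metrics under electrical stimulation.

Deflection traces become force traces through the pillar spring constant
(``F = k * delta``, per pillar; the two-pillar total is their sum, following
the convention that a 76 uN static contraction corresponds to 38 uN per
pillar).  Stimulation protocols are epoch schedules: low-frequency pulses
(1 Hz, 10 ms) evoke discrete twitches whose amplitude is the mean
peak-above-baseline; high-frequency trains (90 Hz, 10 ms) fuse into a
tetanic plateau whose force is the mean of the late-epoch plateau above
baseline.  The fusion ratio (tetanic/twitch) quantifies temporal summation.

A linear alpha-function kernel model simulates contraction traces for
benchmarking: each stimulus pulse contributes
``A * (exp(-t/tau_decay) - exp(-t/tau_rise))`` (peak-normalized), and
pulses sum linearly — a deliberate simplification of excitation-contraction
dynamics that reproduces twitch trains, fusion, and the force-frequency
relation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import spearmanr

__all__ = [
    "StimulusProtocol",
    "Epoch",
    "ForceTrace",
    "ContractionMetrics",
    "TwitchKernel",
    "force_trace",
    "twitch_metrics",
    "tetanic_metrics",
    "contraction_metrics",
    "simulate_contraction",
    "dose_response_summary",
    "effect_sizes",
]

TWITCH_FREQUENCY_HZ = 1.0
TETANIC_FREQUENCY_HZ = 90.0
DEFAULT_PULSE_WIDTH_MS = 10.0
BASELINE_LOOKBACK_S = 2.0


@dataclass(frozen=True)
class Epoch:
    """One stimulation epoch: pulses at ``frequency_hz`` in [t_start, t_end)."""

    t_start_s: float
    t_end_s: float
    frequency_hz: float

    def __post_init__(self) -> None:
        if self.t_end_s <= self.t_start_s:
            raise ValueError("epoch must have positive duration")
        if self.frequency_hz <= 0:
            raise ValueError("epoch frequency must be positive")

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s

    def pulse_times(self) -> np.ndarray:
        # pulses at t_start + k/f for all k with k/f < duration (k = 0 always fires)
        n = int(np.ceil(self.duration_s * self.frequency_hz - 1e-12))
        return self.t_start_s + np.arange(max(n, 1)) / self.frequency_hz


@dataclass(frozen=True)
class StimulusProtocol:
    """Electrical stimulation descriptor with an epoch schedule."""

    epochs: tuple
    pulse_width_ms: float = DEFAULT_PULSE_WIDTH_MS
    amplitude_v: float = 40.0
    electrode_gap_mm: float = 22.0

    def __post_init__(self) -> None:
        epochs = tuple(
            e if isinstance(e, Epoch) else Epoch(*e) for e in self.epochs
        )
        object.__setattr__(self, "epochs", epochs)
        if not epochs:
            raise ValueError("protocol needs at least one epoch")
        if self.pulse_width_ms <= 0:
            raise ValueError("pulse width must be positive")
        ordered = sorted(epochs, key=lambda e: e.t_start_s)
        for a, b in zip(ordered, ordered[1:]):
            if b.t_start_s < a.t_end_s:
                raise ValueError("epochs must not overlap")

    @classmethod
    def single(
        cls,
        frequency_hz: float,
        duration_s: float,
        t_start_s: float = 2.0,
        **kwargs,
    ) -> "StimulusProtocol":
        """One epoch preceded by a quiescent baseline period."""
        return cls(
            epochs=(Epoch(t_start_s, t_start_s + duration_s, frequency_hz),),
            **kwargs,
        )

    @classmethod
    def frequency_sweep(
        cls,
        frequencies_hz=(0.5, 1.0, 2.0, 3.0, 90.0),
        epoch_duration_s: float = 10.0,
        gap_s: float = 2.0,
        **kwargs,
    ) -> "StimulusProtocol":
        """Stepwise sweep, one epoch per frequency with quiescent gaps."""
        epochs = []
        t = gap_s
        for f in frequencies_hz:
            epochs.append(Epoch(t, t + epoch_duration_s, f))
            t += epoch_duration_s + gap_s
        return cls(epochs=tuple(epochs), **kwargs)

    def epoch_at(self, frequency_hz: float) -> Epoch:
        for e in self.epochs:
            if np.isclose(e.frequency_hz, frequency_hz):
                return e
        raise ValueError(f"no epoch at {frequency_hz} Hz in protocol")


@dataclass(frozen=True)
class ForceTrace:
    """Per-pillar force time series in uN; total is the two-pillar sum."""

    time_s: np.ndarray
    left_force_un: np.ndarray
    right_force_un: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        l = np.asarray(self.left_force_un, dtype=float)
        r = np.asarray(self.right_force_un, dtype=float)
        if not (t.shape == l.shape == r.shape) or t.ndim != 1:
            raise ValueError("force trace arrays must be 1-D and equal length")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "left_force_un", l)
        object.__setattr__(self, "right_force_un", r)

    @property
    def total_force_un(self) -> np.ndarray:
        return self.left_force_un + self.right_force_un

    @property
    def mean_pillar_force_un(self) -> np.ndarray:
        return 0.5 * self.total_force_un

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_s)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "left_force_uN": self.left_force_un,
                "right_force_uN": self.right_force_un,
                "total_force_uN": self.total_force_un,
            }
        )


@dataclass(frozen=True)
class ContractionMetrics:
    """Twitch/tetanus summary for one tissue (per-pillar forces, uN)."""

    baseline_force_un: float
    twitch_amplitude_un: float | None = None
    tetanic_force_un: float | None = None
    tetanic_ripple_un: float | None = None

    @property
    def fusion_ratio(self) -> float | None:
        if self.twitch_amplitude_un in (None, 0.0) or self.tetanic_force_un is None:
            return None
        return self.tetanic_force_un / self.twitch_amplitude_un


@dataclass(frozen=True)
class TwitchKernel:
    """Alpha-function twitch: peak amplitude (uN), rise and decay taus (s)."""

    amplitude_un: float = 5.0
    tau_rise_s: float = 0.02
    tau_decay_s: float = 0.2

    def __post_init__(self) -> None:
        if self.tau_rise_s <= 0 or self.tau_decay_s <= 0:
            raise ValueError("kernel time constants must be positive")
        if self.tau_decay_s <= self.tau_rise_s:
            raise ValueError("decay tau must exceed rise tau")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Peak-normalized double-exponential, scaled to ``amplitude_un``."""
        t = np.asarray(t, dtype=float)
        shape = np.where(
            t >= 0, np.exp(-t / self.tau_decay_s) - np.exp(-t / self.tau_rise_s), 0.0
        )
        # analytic peak of the double exponential
        tp = (
            self.tau_rise_s
            * self.tau_decay_s
            / (self.tau_decay_s - self.tau_rise_s)
            * np.log(self.tau_decay_s / self.tau_rise_s)
        )
        peak = np.exp(-tp / self.tau_decay_s) - np.exp(-tp / self.tau_rise_s)
        return self.amplitude_un * shape / peak


def force_trace(deflection, stiffness_k_un_per_um: float) -> ForceTrace:
    """Convert a :class:`~pillarforce.tracking.DeflectionTrace` to forces."""
    if stiffness_k_un_per_um <= 0:
        raise ValueError("spring constant must be positive")
    return ForceTrace(
        time_s=deflection.time_s,
        left_force_un=stiffness_k_un_per_um * deflection.left_deflection_um,
        right_force_un=stiffness_k_un_per_um * deflection.right_deflection_um,
    )


def _baseline(force: np.ndarray, time: np.ndarray, epoch: Epoch) -> float:
    """Median force over the lookback window preceding the epoch.

    If the recording starts at the epoch (no pre-stimulus samples), fall
    back to the epoch's rolling minimum proxy: the 5th percentile.
    """
    pre = (time >= epoch.t_start_s - BASELINE_LOOKBACK_S) & (time < epoch.t_start_s)
    if pre.sum() >= 3:
        return float(np.median(force[pre]))
    in_epoch = (time >= epoch.t_start_s) & (time < epoch.t_end_s)
    return float(np.percentile(force[in_epoch], 5))


def _noise_mad(force: np.ndarray) -> float:
    """Robust noise scale: MAD of the first difference, rescaled."""
    d = np.diff(force)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def twitch_metrics(
    force: ForceTrace,
    protocol: StimulusProtocol,
    frequency_hz: float = TWITCH_FREQUENCY_HZ,
    channel: str = "mean_pillar",
) -> ContractionMetrics:
    """Twitch amplitude: mean per-period peak above the pre-epoch baseline.

    Peaks are local maxima with prominence >= 3x the trace noise MAD and
    separation >= half a stimulation period.  A trace with no resolvable
    peaks yields zero amplitude with a warning rather than an error.
    """
    epoch = protocol.epoch_at(frequency_hz)
    if epoch.duration_s * frequency_hz < 3:
        raise ValueError("twitch epoch must contain at least 3 periods")
    y = _channel(force, channel)
    t = force.time_s
    base = _baseline(y, t, epoch)
    in_epoch = (t >= epoch.t_start_s) & (t < epoch.t_end_s)
    seg = y[in_epoch]
    fs = force.sampling_rate_hz
    noise = _noise_mad(seg)
    min_dist = max(1, int(0.5 / frequency_hz * fs))
    prominence = max(3.0 * noise, 1e-12)
    peaks, _ = find_peaks(seg, prominence=prominence, distance=min_dist)
    if peaks.size == 0:
        warnings.warn("no twitch peaks above noise floor; amplitude set to 0", stacklevel=2)
        amplitude = 0.0
    else:
        amplitude = float(np.mean(seg[peaks]) - base)
    return ContractionMetrics(baseline_force_un=base, twitch_amplitude_un=amplitude)


def tetanic_metrics(
    force: ForceTrace,
    protocol: StimulusProtocol,
    frequency_hz: float = TETANIC_FREQUENCY_HZ,
    channel: str = "mean_pillar",
    relaxation_time_s: float = 0.5,
) -> ContractionMetrics:
    """Tetanic force: mean of the plateau (last half of the epoch) above baseline.

    The first half of the epoch is excluded as the fusion transient.
    Plateau ripple (peak-to-trough) is reported alongside.  Epochs shorter
    than twice the twitch relaxation time trigger an unreliable-plateau
    warning.
    """
    epoch = protocol.epoch_at(frequency_hz)
    if epoch.duration_s < 2.0 * relaxation_time_s:
        warnings.warn(
            "tetanic epoch shorter than twice the relaxation time: plateau "
            "estimate unreliable",
            stacklevel=2,
        )
    y = _channel(force, channel)
    t = force.time_s
    base = _baseline(y, t, epoch)
    plateau_start = epoch.t_start_s + 0.5 * epoch.duration_s
    sel = (t >= plateau_start) & (t < epoch.t_end_s)
    plateau = y[sel]
    return ContractionMetrics(
        baseline_force_un=base,
        tetanic_force_un=float(np.mean(plateau) - base),
        tetanic_ripple_un=float(np.ptp(plateau)),
    )


def contraction_metrics(
    force: ForceTrace, protocol: StimulusProtocol, channel: str = "mean_pillar"
) -> ContractionMetrics:
    """Combined twitch + tetanus summary when both epochs are present."""
    tw = twitch_metrics(force, protocol, channel=channel)
    te = tetanic_metrics(force, protocol, channel=channel)
    return ContractionMetrics(
        baseline_force_un=tw.baseline_force_un,
        twitch_amplitude_un=tw.twitch_amplitude_un,
        tetanic_force_un=te.tetanic_force_un,
        tetanic_ripple_un=te.tetanic_ripple_un,
    )


def _channel(force: ForceTrace, channel: str) -> np.ndarray:
    if channel == "left":
        return force.left_force_un
    if channel == "right":
        return force.right_force_un
    if channel == "total":
        return force.total_force_un
    if channel == "mean_pillar":
        return force.mean_pillar_force_un
    raise ValueError(f"unknown channel {channel!r}")


def simulate_contraction(
    protocol: StimulusProtocol,
    kernel: TwitchKernel = TwitchKernel(),
    noise_sigma_un: float = 0.0,
    seed: int | None = None,
    sampling_rate_hz: float = 100.0,
    baseline_un: float = 0.0,
    duration_s: float | None = None,
) -> ForceTrace:
    """Simulate a per-pillar force trace from the linear kernel model.

    Each protocol pulse adds one alpha-function twitch; pulses sum
    linearly, so high-frequency trains fuse into a plateau.  Gaussian noise
    of ``noise_sigma_un`` is added independently per pillar; the trace is
    deterministic given the seed.  Both pillars carry the same programmed
    force (symmetric contraction).
    """
    if duration_s is None:
        duration_s = max(e.t_end_s for e in protocol.epochs) + 2.0
    t = np.arange(0.0, duration_s, 1.0 / sampling_rate_hz)
    y = np.full_like(t, baseline_un)
    for epoch in protocol.epochs:
        for tp in epoch.pulse_times():
            y += kernel.evaluate(t - tp)
    rng = np.random.default_rng(seed)
    left = y + (rng.normal(0.0, noise_sigma_un, t.size) if noise_sigma_un > 0 else 0.0)
    right = y + (rng.normal(0.0, noise_sigma_un, t.size) if noise_sigma_un > 0 else 0.0)
    return ForceTrace(time_s=t, left_force_un=left, right_force_un=right)


def dose_response_summary(
    metrics: pd.DataFrame,
    value_column: str = "force_un",
    dose_column: str = "dose",
    vehicle_label="vehicle",
) -> tuple[pd.DataFrame, str]:
    """Per-dose force summaries and a monotonic-trend flag.

    ``metrics`` holds one row per tissue with a dose label (the vehicle
    group is identified by ``vehicle_label``; other labels must be numeric
    doses).  Returns a table of mean, SD, n and the ratio of each dose mean
    to the vehicle mean, plus a trend flag ("increasing" / "decreasing" /
    "none") from the sign of the Spearman correlation between dose rank and
    group mean (vehicle entering as dose 0).
    """
    if vehicle_label not in set(metrics[dose_column]):
        raise ValueError(f"missing vehicle group {vehicle_label!r}")
    doses = sorted(d for d in set(metrics[dose_column]) if d != vehicle_label)
    if len(doses) < 2:
        raise ValueError("need at least two dose groups beyond vehicle")

    rows = []
    vehicle_mean = float(
        metrics.loc[metrics[dose_column] == vehicle_label, value_column].mean()
    )
    for dose in [vehicle_label] + doses:
        vals = metrics.loc[metrics[dose_column] == dose, value_column]
        rows.append(
            {
                dose_column: dose,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n": int(len(vals)),
                "ratio_to_vehicle": float(vals.mean()) / vehicle_mean
                if vehicle_mean != 0
                else np.nan,
            }
        )
    table = pd.DataFrame(rows)

    numeric_doses = np.array([0.0] + [float(d) for d in doses])
    means = table["mean"].to_numpy()
    if np.allclose(means, means[0]):
        trend = "none"
    else:
        rho = spearmanr(numeric_doses, means).statistic
        if np.isnan(rho) or rho == 0:
            trend = "none"
        else:
            trend = "increasing" if rho > 0 else "decreasing"
    return table, trend


def effect_sizes(group_a, group_b) -> tuple[float, float]:
    """Cohen's d (pooled SD) and eta-squared for a two-group comparison.

    ``d = (mean_a - mean_b) / s_pooled`` with the (n-1)-weighted pooled SD;
    ``eta^2 = SS_between / SS_total``.  Swapping the groups flips the sign
    of d and leaves eta-squared unchanged.  Zero pooled variance is
    undefined and raises.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    na, nb = a.size, b.size
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2))
    if pooled == 0:
        raise ValueError("zero pooled variance: effect size undefined")
    d = (a.mean() - b.mean()) / pooled

    grand = np.concatenate([a, b]).mean()
    ss_between = na * (a.mean() - grand) ** 2 + nb * (b.mean() - grand) ** 2
    ss_total = float(((np.concatenate([a, b]) - grand) ** 2).sum())
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    return float(d), float(eta2)
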