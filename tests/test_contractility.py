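"""Force conversion, twitch/tetanus extraction, dose response, effect sizes."""

import numpy as np
import pandas as pd
import pytest

from pillarforce.contractility import (
    Epoch,
    ForceTrace,
    StimulusProtocol,
    TwitchKernel,
    contraction_metrics,
    dose_response_summary,
    effect_sizes,
    force_trace,
    simulate_contraction,
    tetanic_metrics,
    twitch_metrics,
)
from pillarforce.tracking import DeflectionTrace

TWITCH_PROTOCOL = StimulusProtocol(epochs=((2.0, 8.0, 1.0),))
ASSAY_PROTOCOL = StimulusProtocol(epochs=((2.0, 8.0, 1.0), (10.0, 13.0, 90.0)))


def _deflection(values, dt=0.1):
    n = len(values)
    v = np.asarray(values, dtype=float)
    return DeflectionTrace(
        time_s=np.arange(n) * dt,
        left_deflection_um=v,
        right_deflection_um=v,
        interpillar_distance_um=np.full(n, 2600.0),
    )


class TestForceTrace:
    def test_zero_deflection_zero_force(self):
        ft = force_trace(_deflection(np.zeros(10)), 0.249)
        assert np.all(ft.total_force_un == 0.0)

    def test_calibrated_constant_deflection(self):
        ft = force_trace(_deflection(np.full(10, 100.0)), 0.249)
        np.testing.assert_allclose(ft.left_force_un, 24.9)
        np.testing.assert_allclose(ft.total_force_un, 49.8)

    def test_force_scales_with_spring_constant(self):
        d = _deflection(np.linspace(0, 50, 20))
        np.testing.assert_allclose(
            force_trace(d, 0.498).total_force_un,
            2.0 * force_trace(d, 0.249).total_force_un,
        )

    def test_reference_load_split_between_two_pillars(self):
        """A 76 uN total contraction corresponds to 38 uN per pillar."""
        ft = ForceTrace(
            time_s=np.arange(3.0),
            left_force_un=np.full(3, 38.0),
            right_force_un=np.full(3, 38.0),
        )
        np.testing.assert_allclose(ft.total_force_un, 76.0)
        np.testing.assert_allclose(ft.mean_pillar_force_un, 38.0)

    def test_nonpositive_spring_constant_rejected(self):
        with pytest.raises(ValueError):
            force_trace(_deflection(np.zeros(5)), 0.0)


class TestProtocol:
    def test_overlapping_epochs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            StimulusProtocol(epochs=((0.0, 5.0, 1.0), (4.0, 8.0, 90.0)))

    def test_sweep_covers_requested_frequencies(self):
        p = StimulusProtocol.frequency_sweep()
        assert [e.frequency_hz for e in p.epochs] == [0.5, 1.0, 2.0, 3.0, 90.0]

    def test_single_pulse_fires_even_in_short_epoch(self):
        assert Epoch(0.0, 1.0, 0.5).pulse_times().size == 1


class TestSimulation:
    def test_single_pulse_peak_equals_kernel_amplitude(self):
        kernel = TwitchKernel(amplitude_un=5.0)
        trace = simulate_contraction(
            StimulusProtocol(epochs=((2.0, 3.0, 0.5),)),
            kernel=kernel,
            sampling_rate_hz=1000.0,
        )
        assert trace.left_force_un.max() == pytest.approx(5.0, rel=0.01)

    def test_deterministic_given_seed(self):
        a = simulate_contraction(ASSAY_PROTOCOL, noise_sigma_un=0.1, seed=5)
        b = simulate_contraction(ASSAY_PROTOCOL, noise_sigma_un=0.1, seed=5)
        np.testing.assert_array_equal(a.left_force_un, b.left_force_un)
        np.testing.assert_array_equal(a.right_force_un, b.right_force_un)

    def test_high_frequency_plateau_matches_geometric_series_limit(self):
        """Fused plateau equals rate x kernel integral (linear summation).

        For pulses every 1/f with decay tau >> 1/f, the summed kernel
        plateau converges to f * integral(K) = f * A_norm * (tau_d - tau_r).
        """
        kernel = TwitchKernel(amplitude_un=5.0, tau_rise_s=0.02, tau_decay_s=0.2)
        f = 90.0
        trace = simulate_contraction(
            StimulusProtocol(epochs=((1.0, 6.0, f),)), kernel=kernel,
            sampling_rate_hz=2000.0,
        )
        sel = (trace.time_s >= 4.0) & (trace.time_s < 6.0)
        plateau = trace.left_force_un[sel].mean()
        tp = (
            kernel.tau_rise_s * kernel.tau_decay_s
            / (kernel.tau_decay_s - kernel.tau_rise_s)
            * np.log(kernel.tau_decay_s / kernel.tau_rise_s)
        )
        peak = np.exp(-tp / kernel.tau_decay_s) - np.exp(-tp / kernel.tau_rise_s)
        expected = f * kernel.amplitude_un / peak * (kernel.tau_decay_s - kernel.tau_rise_s)
        assert plateau == pytest.approx(expected, rel=0.02)
        assert plateau > kernel.amplitude_un  # summation beats a single twitch


class TestTwitchMetrics:
    def test_programmed_amplitude_recovered_within_three_percent(self):
        kernel = TwitchKernel(amplitude_un=8.0)
        trace = simulate_contraction(
            TWITCH_PROTOCOL, kernel=kernel, noise_sigma_un=0.05, seed=3,
            sampling_rate_hz=200.0,
        )
        m = twitch_metrics(trace, TWITCH_PROTOCOL)
        assert m.twitch_amplitude_un == pytest.approx(8.0, rel=0.03)

    def test_flat_trace_gives_zero_amplitude_with_warning(self):
        n = 1500
        trace = ForceTrace(
            time_s=np.arange(n) / 100.0,
            left_force_un=np.zeros(n),
            right_force_un=np.zeros(n),
        )
        with pytest.warns(UserWarning, match="no twitch peaks"):
            m = twitch_metrics(trace, TWITCH_PROTOCOL)
        assert m.twitch_amplitude_un == 0.0

    def test_amplitude_linearity(self):
        amps = []
        for a in (4.0, 8.0):
            trace = simulate_contraction(
                TWITCH_PROTOCOL, kernel=TwitchKernel(amplitude_un=a),
                noise_sigma_un=0.0, seed=0, sampling_rate_hz=200.0,
            )
            amps.append(twitch_metrics(trace, TWITCH_PROTOCOL).twitch_amplitude_un)
        assert amps[1] == pytest.approx(2.0 * amps[0], rel=1e-6)

    def test_baseline_offset_invariance(self):
        """Adding constant pre-tension leaves twitch/tetanus unchanged."""
        trace = simulate_contraction(
            ASSAY_PROTOCOL, kernel=TwitchKernel(amplitude_un=6.0),
            noise_sigma_un=0.02, seed=9, sampling_rate_hz=200.0,
        )
        offset = ForceTrace(
            time_s=trace.time_s,
            left_force_un=trace.left_force_un + 12.5,
            right_force_un=trace.right_force_un + 12.5,
        )
        m0 = contraction_metrics(trace, ASSAY_PROTOCOL)
        m1 = contraction_metrics(offset, ASSAY_PROTOCOL)
        assert m1.twitch_amplitude_un == pytest.approx(m0.twitch_amplitude_un, abs=1e-6)
        assert m1.tetanic_force_un == pytest.approx(m0.tetanic_force_un, abs=1e-6)
        assert m1.baseline_force_un == pytest.approx(m0.baseline_force_un + 12.5, abs=1e-6)


class TestTetanicMetrics:
    def test_fused_plateau_exceeds_single_twitch(self):
        kernel = TwitchKernel(amplitude_un=5.0, tau_decay_s=0.2)
        trace = simulate_contraction(
            ASSAY_PROTOCOL, kernel=kernel, noise_sigma_un=0.02, seed=4,
            sampling_rate_hz=400.0,
        )
        m = contraction_metrics(trace, ASSAY_PROTOCOL)
        assert m.tetanic_force_un > m.twitch_amplitude_un

    def test_flat_trace_gives_zero(self):
        n = 3000
        trace = ForceTrace(
            time_s=np.arange(n) / 200.0,
            left_force_un=np.zeros(n),
            right_force_un=np.zeros(n),
        )
        m = tetanic_metrics(trace, ASSAY_PROTOCOL)
        assert m.tetanic_force_un == 0.0

    def test_force_frequency_relation_nondecreasing(self):
        """Mean force grows with stimulation frequency on the kernel model."""
        kernel = TwitchKernel(amplitude_un=5.0)
        means = []
        for f in (0.5, 1.0, 2.0, 3.0, 90.0):
            p = StimulusProtocol.single(f, 6.0)
            trace = simulate_contraction(p, kernel=kernel, sampling_rate_hz=400.0)
            e = p.epoch_at(f)
            sel = (trace.time_s >= e.t_start_s + 3.0) & (trace.time_s < e.t_end_s)
            means.append(trace.mean_pillar_force_un[sel].mean())
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_fusion_ratio_higher_at_tetanic_frequency(self):
        """With tau_decay = 200 ms, 90 Hz fuses while 1 Hz does not."""
        kernel = TwitchKernel(amplitude_un=5.0, tau_decay_s=0.2)
        trace = simulate_contraction(
            ASSAY_PROTOCOL, kernel=kernel, noise_sigma_un=0.0, seed=0,
            sampling_rate_hz=400.0,
        )
        m = contraction_metrics(trace, ASSAY_PROTOCOL)
        # "fusion ratio at 1 Hz" is plateau/twitch computed with the twitch
        # epoch standing in for the tetanic one: no summation, ratio ~1
        twitch_epoch_plateau = tetanic_metrics(
            trace, ASSAY_PROTOCOL, frequency_hz=1.0
        ).tetanic_force_un
        ratio_1hz = twitch_epoch_plateau / m.twitch_amplitude_un
        assert m.fusion_ratio > ratio_1hz

    def test_short_epoch_warns_unreliable_plateau(self):
        p = StimulusProtocol(epochs=((2.0, 2.5, 90.0),))
        trace = simulate_contraction(p, sampling_rate_hz=400.0)
        with pytest.warns(UserWarning, match="plateau"):
            tetanic_metrics(trace, p)


class TestDoseResponse:
    def _metrics(self, means, n=4, sd=0.2, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for dose, mu in means.items():
            for v in rng.normal(mu, sd, n):
                rows.append({"dose": dose, "force_un": v})
        return pd.DataFrame(rows)

    def test_decreasing_scenario_flagged(self):
        df = self._metrics({"vehicle": 10.0, 0.01: 9.0, 0.1: 7.0, 1.0: 4.0})
        _, trend = dose_response_summary(df)
        assert trend == "decreasing"

    def test_increasing_scenario_flagged(self):
        df = self._metrics({"vehicle": 10.0, 0.01: 10.5, 0.1: 12.0, 1.0: 13.5})
        table, trend = dose_response_summary(df)
        assert trend == "increasing"
        assert table.loc[table["dose"] == 1.0, "ratio_to_vehicle"].iloc[0] > 1.0

    def test_identical_groups_give_unit_ratios_and_no_trend(self):
        df = self._metrics({"vehicle": 10.0, 0.1: 10.0, 1.0: 10.0}, sd=0.0)
        table, trend = dose_response_summary(df)
        assert trend == "none"
        np.testing.assert_allclose(table["ratio_to_vehicle"], 1.0)

    def test_missing_vehicle_rejected(self):
        df = self._metrics({0.1: 10.0, 1.0: 8.0})
        with pytest.raises(ValueError, match="vehicle"):
            dose_response_summary(df)


class TestEffectSizes:
    def test_identical_groups_with_spread_give_zero(self):
        d, eta2 = effect_sizes([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert eta2 == 0.0

    def test_hand_computed_fixture(self):
        # pooled SD = sqrt(0.5), shift = -1 => d = -sqrt(2);
        # SS_between = 2*(0.5)^2 + 2*(0.5)^2 = 1, SS_total = 2 => eta2 = 0.5
        d, eta2 = effect_sizes([0.0, 1.0], [1.0, 2.0])
        assert d == pytest.approx(-np.sqrt(2.0))
        assert eta2 == pytest.approx(0.5)

    def test_swapping_groups_flips_d_only(self):
        a, b = [0.0, 0.5, 1.0, 1.5], [2.0, 2.5, 3.0, 3.5]
        d_ab, eta_ab = effect_sizes(a, b)
        d_ba, eta_ba = effect_sizes(b, a)
        assert d_ba == pytest.approx(-d_ab)
        assert eta_ba == pytest.approx(eta_ab)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="pooled variance"):
            effect_sizes([1.0, 1.0], [2.0, 2.0])

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            effect_sizes([1.0], [2.0, 3.0])
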