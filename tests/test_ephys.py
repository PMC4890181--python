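"""Electrophysiology analyses: histograms, idealization, conductance, GHK."""
import numpy as np
import pytest
from hypothesis import assume, given, strategies as st

from thylakoid_biophys import (
    CurrentTrace,
    IonicCondition,
    ephys,
    kcl_gradient,
    symmetric_kcl,
    thermal_voltage_mv,
)
from thylakoid_biophys import synthetic_data as synth
from thylakoid_biophys.errors import (
    InsufficientDataError,
    NoOpenEventsError,
    UnidentifiableError,
)


def _trace_from(current, ionic=None, v_mv=80.0, fs=1000.0):
    current = np.asarray(current, dtype=float)
    return CurrentTrace(
        time=np.arange(current.size) / fs,
        current=current,
        holding_potential_mv=v_mv,
        ionic=ionic or symmetric_kcl(),
        sampling_rate_hz=fs,
    )


class TestAmplitudeHistogram:
    def test_constant_trace_occupies_single_bin(self):
        hist = ephys.build_amplitude_histogram(_trace_from(np.zeros(500)), 0.1)
        assert np.count_nonzero(hist.counts) == 1
        assert hist.n_samples == 500

    def test_counts_conserve_sample_number(self):
        rng = np.random.default_rng(0)
        trace = _trace_from(rng.normal(0, 1, 10_000))
        hist = ephys.build_amplitude_histogram(trace, 0.05)
        assert hist.n_samples == 10_000

    def test_two_level_trace_gives_two_bins_at_unitary_separation(self):
        # Noiseless alternation between 0 and 7.69 pA (96.1 pS at +80 mV).
        level = 96.1 * 80.0 / 1000.0
        current = np.tile([0.0, level], 500)
        hist = ephys.build_amplitude_histogram(_trace_from(current), 0.1)
        occupied = hist.bin_centers[hist.counts > 0]
        assert occupied.size == 2
        assert abs((occupied[1] - occupied[0]) - level) < 0.1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ephys.build_amplitude_histogram(_trace_from([1.0, 2.0]), 0.0)


class TestUnitaryCurrent:
    def test_noiseless_two_level_modes(self):
        current = np.tile([0.0, 7.688], 500)
        hist = ephys.build_amplitude_histogram(_trace_from(current), 0.1)
        assert ephys.estimate_unitary_current(hist) == pytest.approx(7.688, abs=0.1)

    def test_all_closed_raises_no_open_events(self):
        hist = ephys.build_amplitude_histogram(_trace_from(np.zeros(1000)), 0.1)
        with pytest.raises(NoOpenEventsError):
            ephys.estimate_unitary_current(hist)

    def test_pure_noise_raises_no_open_events(self):
        rng = np.random.default_rng(8)
        trace = _trace_from(rng.normal(0.0, 0.8, 200_000))
        hist = ephys.build_amplitude_histogram(trace, 0.1)
        with pytest.raises(NoOpenEventsError):
            ephys.estimate_unitary_current(hist)

    def test_mixture_recovery_within_two_percent(self, positive_branch_traces):
        # 60 s at 5 kHz, noise 0.8 pA: separation recovered to +-2%.
        for trace in positive_branch_traces:
            truth = trace.metadata["truth"]["unitary_current_pa"]
            hist = ephys.build_amplitude_histogram(trace, 0.1)
            est = ephys.estimate_unitary_current(hist)
            assert est == pytest.approx(truth, rel=0.02)

    def test_negative_voltage_gives_signed_estimate(self):
        params = synth.ChannelGatingParams()
        config = synth.RecordingConfig(
            holding_potentials_mv=(-60.0,), duration_s=30.0, seed=13
        )
        (trace,) = synth.simulate_channel_trace(params, config)
        hist = ephys.build_amplitude_histogram(trace, 0.1)
        est = ephys.estimate_unitary_current(hist)
        assert est == pytest.approx(-3.6, rel=0.05)


class TestIdealization:
    def test_alternating_trace_has_half_open_probability(self):
        current = np.tile([0.0, 5.0], 500)
        ideal = ephys.idealize_half_amplitude(_trace_from(current), 5.0)
        assert ideal.open_probability == 0.5

    def test_all_closed_trace_has_zero_open_probability(self):
        ideal = ephys.idealize_half_amplitude(_trace_from(np.zeros(100)), 5.0)
        assert ideal.open_probability == 0.0
        assert len(ideal.segments) == 1

    def test_segments_tile_trace_exactly(self):
        rng = np.random.default_rng(2)
        current = np.where(rng.random(5000) > 0.5, 5.0, 0.0)
        trace = _trace_from(current)
        ideal = ephys.idealize_half_amplitude(trace, 5.0)
        assert ideal.total_time_s == pytest.approx(trace.duration_s, rel=1e-12)
        starts = np.array([s for _, s, _ in ideal.segments])
        durations = np.array([d for _, _, d in ideal.segments])
        assert np.allclose(starts[1:], starts[:-1] + durations[:-1])

    def test_low_noise_labels_match_generator_state_path(self):
        params = synth.ChannelGatingParams()
        config = synth.RecordingConfig(
            holding_potentials_mv=(80.0,), duration_s=20.0,
            noise_sd_pa=0.5, seed=21,  # i/2 = 3.84 pA >> noise
        )
        (trace,) = synth.simulate_channel_trace(params, config)
        i_unit = trace.metadata["truth"]["unitary_current_pa"]
        ideal = ephys.idealize_half_amplitude(trace, i_unit)
        truth_open = trace.true_level > 0
        agreement = np.mean((ideal.labels > 0) == truth_open)
        assert agreement >= 0.99

    def test_substate_level_resolved_with_third_threshold(self):
        current = np.array([0.0, 2.5, 5.0, 5.0, 2.5, 0.0])
        ideal = ephys.idealize_half_amplitude(
            _trace_from(current), 5.0, substate_fraction=0.5
        )
        assert [lvl for lvl, _, _ in ideal.segments] == [
            "closed", "substate", "open", "substate", "closed"
        ]
        assert ideal.open_probability == pytest.approx(4 / 6)

    def test_zero_unitary_current_rejected(self):
        with pytest.raises(ValueError):
            ephys.idealize_half_amplitude(_trace_from(np.zeros(10)), 0.0)


class TestBranchConductance:
    def test_exact_line_recovers_slope_on_both_branches(self):
        voltages = [-80.0, -40.0, 40.0, 80.0]
        points = [(v, 0.1 * v) for v in voltages]  # 100 pS line
        fit = ephys.fit_branch_conductance(points)
        assert fit.gamma_pos_ps == pytest.approx(100.0)
        assert fit.gamma_neg_ps == pytest.approx(100.0)

    def test_generated_positive_branch_recovers_gamma(self, positive_branch_traces):
        points = []
        for trace in positive_branch_traces:
            hist = ephys.build_amplitude_histogram(trace, 0.1)
            points.append(
                (trace.holding_potential_mv, ephys.estimate_unitary_current(hist))
            )
        fit = ephys.fit_branch_conductance(points)
        assert fit.gamma_pos_ps == pytest.approx(96.1, rel=0.05)
        assert fit.gamma_neg_ps is None

    def test_empty_branch_marked_unavailable(self):
        fit = ephys.fit_branch_conductance([(40.0, 4.0), (80.0, 8.0)])
        assert fit.gamma_neg_ps is None
        assert fit.gamma_pos_ps == pytest.approx(100.0)

    def test_single_point_branch_raises(self):
        with pytest.raises(InsufficientDataError):
            ephys.fit_branch_conductance([(40.0, 4.0), (80.0, 8.0), (-40.0, -2.4)])

    def test_single_mode_fits_one_slope_across_branches(self):
        points = [(v, 0.0287 * v) for v in (-80.0, -40.0, 40.0, 80.0)]
        fit = ephys.fit_branch_conductance(points, mode="single")
        assert fit.gamma_pos_ps == pytest.approx(28.7)
        assert fit.gamma_pos_ps == fit.gamma_neg_ps


class TestGhk:
    def test_symmetric_bath_reverses_at_zero(self, kcl_100):
        for p in (0.0, 0.17, 1.0, 5.0):
            assert ephys.ghk_reversal_potential(p, kcl_100) == pytest.approx(0.0)

    def test_nernst_limit_for_pure_anion_channel(self, kcl_300_100):
        # p_ratio = 0 collapses to the Cl- Nernst potential, (RT/F) ln 3.
        v = ephys.ghk_reversal_potential(0.0, kcl_300_100)
        assert v == pytest.approx(thermal_voltage_mv() * np.log(3.0), abs=1e-9)
        assert v == pytest.approx(28.2, abs=0.05)

    def test_equal_permeabilities_cancel_in_salt_gradient(self, kcl_300_100):
        assert ephys.ghk_reversal_potential(1.0, kcl_300_100) == pytest.approx(0.0)

    def test_paper_ratio_round_trip(self, kcl_300_100):
        v = ephys.ghk_reversal_potential(0.17, kcl_300_100)
        assert ephys.fit_permeability_ratio(v, kcl_300_100).p_ratio == pytest.approx(
            0.17, abs=1e-12
        )

    def test_nernst_limit_inverts_to_zero(self, kcl_300_100):
        v_cl = thermal_voltage_mv() * np.log(3.0)
        assert ephys.fit_permeability_ratio(v_cl, kcl_300_100).p_ratio == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_symmetric_condition_unidentifiable(self, kcl_100):
        with pytest.raises(UnidentifiableError):
            ephys.fit_permeability_ratio(5.0, kcl_100)

    def test_vrev_outside_attainable_range_rejected(self, kcl_300_100):
        with pytest.raises(ValueError):
            ephys.fit_permeability_ratio(35.0, kcl_300_100)
        with pytest.raises(ValueError):
            ephys.fit_permeability_ratio(-35.0, kcl_300_100)

    @given(p=st.floats(0.0, 10.0))
    def test_forward_inverse_identity(self, p):
        ionic = kcl_gradient(300.0, 100.0)
        v = ephys.ghk_reversal_potential(p, ionic)
        assert ephys.fit_permeability_ratio(v, ionic).p_ratio == pytest.approx(
            p, abs=1e-9, rel=1e-9
        )

    @given(
        p=st.lists(st.floats(0.0, 10.0), min_size=2, max_size=2, unique=True)
    )
    def test_strict_monotonicity_in_p_ratio(self, p):
        assume(abs(p[1] - p[0]) > 1e-9)
        ionic = kcl_gradient(300.0, 100.0)
        v0 = ephys.ghk_reversal_potential(p[0], ionic)
        v1 = ephys.ghk_reversal_potential(p[1], ionic)
        assert (v1 - v0) * (p[1] - p[0]) < 0  # decreasing for this gradient

    def test_ghk_current_zero_crossing_matches_voltage_equation(self, kcl_300_100):
        # The constant-field flux model and the voltage equation must agree
        # on the reversal potential for any permeability ratio.
        for p in (0.05, 0.17, 0.8):
            v_eq = ephys.ghk_reversal_potential(p, kcl_300_100)
            v = np.linspace(v_eq - 5.0, v_eq + 5.0, 2001)
            i = ephys.ghk_current(v, kcl_300_100, {"K": p, "Cl": 1.0})
            v_cross = ephys.interpolate_reversal_potential(v, i)
            assert v_cross == pytest.approx(v_eq, abs=1e-4)

    def test_ghk_current_continuous_through_zero_mv(self, kcl_300_100):
        i = ephys.ghk_current(
            np.array([-1e-6, 0.0, 1e-6]), kcl_300_100, {"K": 0.17, "Cl": 1.0}
        )
        assert np.all(np.isfinite(i))
        assert abs(i[0] - i[2]) < 1e-6 * abs(i[0]) + 1e-9


class TestReversalEstimation:
    def test_linear_interpolation_on_exact_line(self):
        v = np.array([-10.0, 0.0, 10.0, 20.0])
        i = 0.5 * (v - 4.0)
        assert ephys.interpolate_reversal_potential(v, i) == pytest.approx(4.0)

    def test_no_crossing_raises(self):
        with pytest.raises(ValueError):
            ephys.interpolate_reversal_potential([0.0, 10.0], [1.0, 2.0])

    def test_ghk_shape_estimator_recovers_vrev_from_noisy_iv(self, kcl_300_100):
        v = np.linspace(-60, 60, 11)
        ideal = ephys.ghk_current(v, kcl_300_100, {"K": 0.17, "Cl": 1.0})
        rng = np.random.default_rng(31)
        noisy = np.mean(
            [ideal + rng.normal(0, 0.05 * np.max(np.abs(ideal)), v.size)
             for _ in range(3)],
            axis=0,
        )
        v_rev = ephys.estimate_reversal_potential(v, noisy, kcl_300_100)
        v_true = ephys.ghk_reversal_potential(0.17, kcl_300_100)
        assert v_rev == pytest.approx(v_true, abs=1.5)


class TestEndToEndRecovery:
    def test_generate_histogram_unitary_conductance_chain(self):
        # Full-chain property: recovery within +-5% at noise <= 0.1 i,
        # 60-s traces at 5 kHz.
        params = synth.ChannelGatingParams(gamma_pos_ps=96.1, gamma_neg_ps=60.0)
        config = synth.RecordingConfig(
            holding_potentials_mv=(-80.0, -60.0, 60.0, 80.0),
            duration_s=60.0, sampling_rate_hz=5000.0, noise_sd_pa=0.35,
            seed=77,
        )
        points = []
        for trace in synth.simulate_channel_trace(params, config):
            hist = ephys.build_amplitude_histogram(trace, 0.1)
            points.append(
                (trace.holding_potential_mv, ephys.estimate_unitary_current(hist))
            )
        fit = ephys.fit_branch_conductance(points)
        assert fit.gamma_pos_ps == pytest.approx(96.1, rel=0.05)
        assert fit.gamma_neg_ps == pytest.approx(60.0, rel=0.05)
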