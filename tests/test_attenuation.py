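"""Insertion-loss and echo-mode attenuation, backscatter fraction, and the
speed-of-sound sanity check."""

import math

import numpy as np
import pytest

from ucachar.attenuation import (
    CuvetteGeometry,
    LinearRegimeWarning,
    attenuation_echo_mode,
    attenuation_from_records,
    attenuation_from_replicates,
    attenuation_through_transmission,
    linear_backscatter_fraction,
    mean_reflector_level,
    reflection_coefficient,
    reflection_corrected_transmit,
    sound_speed_difference,
)
from ucachar.roi import Rect
from ucachar.synthetic import (
    SimulationConfig,
    simulate_reflector_stacks,
    simulate_transmission_pair,
    simulate_transmission_replicates,
)


class TestInsertionLossFormula:
    def test_identity_medium_zero(self):
        assert attenuation_through_transmission(1.0, 1.0) == 0.0

    def test_ratio_ten_gives_20dB_per_cm(self):
        assert attenuation_through_transmission(10.0, 1.0) == pytest.approx(20.0)

    def test_transmit_coefficient_shifts(self):
        geom = CuvetteGeometry(T=0.5)
        assert attenuation_through_transmission(2.0, 1.0, geom) == pytest.approx(0.0)

    def test_antisymmetric_in_amplitudes(self):
        a = attenuation_through_transmission(3.7, 1.2)
        b = attenuation_through_transmission(1.2, 3.7)
        assert a == pytest.approx(-b)

    def test_halving_path_doubles_alpha(self):
        full = attenuation_through_transmission(5.0, 1.0, CuvetteGeometry(d=1.0))
        half = attenuation_through_transmission(5.0, 1.0, CuvetteGeometry(d=0.5))
        assert half == pytest.approx(2 * full)

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(ValueError):
            attenuation_through_transmission(0.0, 1.0)


class TestRoundTrip:
    def test_recovers_antibubble_scale_alpha(self):
        cfg = SimulationConfig(f0=1.0, n_cycles=10, alpha_true=8.7,
                               noise_rms=0.01, seed=21)
        ref, med = simulate_transmission_pair(cfg)
        alpha = attenuation_from_records(ref, med, CuvetteGeometry(d=cfg.d))
        assert alpha == pytest.approx(8.7, abs=0.1)

    def test_replicate_aggregation(self):
        cfg = SimulationConfig(alpha_true=4.4, noise_rms=0.01, n_replicates=5, seed=22)
        result = attenuation_from_replicates(
            simulate_transmission_replicates(cfg), CuvetteGeometry(d=cfg.d)
        )
        assert result.n_replicates == 5
        assert result.mean == pytest.approx(4.4, abs=0.1)
        assert result.std < 0.1

    def test_low_bias_low_sd_over_seeded_pairs(self):
        vals = []
        for s in range(20):
            cfg = SimulationConfig(alpha_true=4.4, noise_rms=0.01, seed=300 + s)
            ref, med = simulate_transmission_pair(cfg)
            vals.append(attenuation_from_records(ref, med, qc=False))
        vals = np.array(vals)
        assert abs(vals.mean() - 4.4) < 0.02
        assert vals.std(ddof=1) < 0.1

    def test_harmonic_qc_warns_outside_linear_regime(self):
        cfg = SimulationConfig(
            harmonic_ratios={1: 1.0, 2: 0.2}, alpha_true=1.0, noise_rms=0.0, seed=23
        )
        ref, med = simulate_transmission_pair(cfg)
        with pytest.warns(LinearRegimeWarning):
            attenuation_from_records(ref, med)


class TestEchoMode:
    def test_equal_gray_levels_zero(self):
        assert attenuation_echo_mode(1.0, 1.0) == 0.0

    def test_ratio_ten_halved_by_two_way_path(self):
        assert attenuation_echo_mode(10.0, 1.0, CuvetteGeometry(d=1.0, path_factor=2)) == pytest.approx(10.0)

    def test_requires_two_way_geometry(self):
        with pytest.raises(ValueError, match="path_factor=2"):
            attenuation_echo_mode(1.0, 1.0, CuvetteGeometry(path_factor=1))

    def test_reflector_clip_round_trip(self):
        cfg = SimulationConfig(alpha_true=2.8, noise_rms=0.005, seed=31)
        sal, ca = simulate_reflector_stacks(cfg, n_frames=100)
        roi = Rect(0, 18, 32, 22)
        alpha = attenuation_echo_mode(
            mean_reflector_level(sal, roi),
            mean_reflector_level(ca, roi),
            CuvetteGeometry(d=cfg.d, path_factor=2),
        )
        assert alpha == pytest.approx(2.8, abs=0.1)

    def test_agrees_with_through_transmission_on_same_medium(self):
        # same synthetic medium, matched pulse shapes: the two estimators agree
        cfg = SimulationConfig(alpha_true=2.8, noise_rms=0.005, seed=32)
        ref, med = simulate_transmission_pair(cfg)
        alpha_t = attenuation_from_records(ref, med, qc=False)
        sal, ca = simulate_reflector_stacks(cfg, n_frames=100)
        roi = Rect(0, 18, 32, 22)
        alpha_e = attenuation_echo_mode(
            mean_reflector_level(sal, roi), mean_reflector_level(ca, roi),
            CuvetteGeometry(d=cfg.d, path_factor=2),
        )
        assert alpha_t == pytest.approx(alpha_e, abs=0.1)


class TestReflectorLevel:
    def test_constant_stack(self):
        frames = np.full((3, 8, 8), 2.5)
        assert mean_reflector_level(frames, Rect(0, 0, 8, 8)) == 2.5

    def test_two_frame_average(self):
        frames = np.stack([np.full((4, 4), 1.0), np.full((4, 4), 3.0)])
        assert mean_reflector_level(frames, Rect(0, 0, 4, 4)) == 2.0

    def test_matches_brute_force_mean(self, rng):
        frames = rng.rayleigh(1.0, (10, 12, 16))
        roi = Rect(3, 2, 9, 7)
        brute = np.mean([frames[i, 2:7, 3:9].mean() for i in range(10)])
        assert mean_reflector_level(frames, roi) == pytest.approx(brute)

    def test_roi_out_of_bounds(self):
        with pytest.raises(ValueError, match="exceeds"):
            mean_reflector_level(np.ones((1, 4, 4)), Rect(0, 0, 8, 8))


class TestBackscatterFraction:
    @pytest.mark.parametrize(
        "backsc, transmit, expected",
        [(1.0, 1.0, 100.0), (0.04, 1.0, 4.0), (0.0, 1.0, 0.0)],
    )
    def test_values(self, backsc, transmit, expected):
        assert linear_backscatter_fraction(backsc, transmit) == pytest.approx(expected)

    def test_nonpositive_transmit_rejected(self):
        with pytest.raises(ValueError):
            linear_backscatter_fraction(1.0, 0.0)


class TestTransmitCorrection:
    def test_unity_reflection_unchanged(self):
        assert reflection_corrected_transmit(0.7, 1.0) == 0.7

    def test_division_by_reflection_coefficient(self):
        assert reflection_corrected_transmit(0.84, 0.84) == pytest.approx(1.0)

    def test_water_aluminum_impedances(self):
        r = reflection_coefficient(1.48, 17.3)
        assert r == pytest.approx((17.3 - 1.48) / (17.3 + 1.48))
        assert r == pytest.approx(0.8424, abs=1e-4)
        assert reflection_corrected_transmit(0.8424, r) == pytest.approx(1.0, abs=1e-4)

    def test_out_of_range_reflection(self):
        with pytest.raises(ValueError):
            reflection_corrected_transmit(1.0, 1.5)


class TestSoundSpeed:
    def test_zero_delay(self):
        assert sound_speed_difference(0.0, 1.0) == 0.0

    def test_protocol_delay_gives_eight_percent(self):
        assert round(sound_speed_difference(0.6, 1.0, 1480.0)) == 8

    def test_doubled_travel_time_fifty_percent(self):
        t_ref_us = 0.01 / 1480.0 * 1e6
        assert sound_speed_difference(t_ref_us, 1.0, 1480.0) == pytest.approx(50.0)

    def test_nonphysical_delay_rejected(self):
        with pytest.raises(ValueError):
            sound_speed_difference(-100.0, 1.0, 1480.0)
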