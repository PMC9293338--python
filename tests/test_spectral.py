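"""Segmenting, spectrum averaging, harmonic extraction and the
nonlinear-scatter dB statistics."""

import itertools
import math

import numpy as np
import pytest

from ucachar.records import AcquisitionRecord
from ucachar.spectral import (
    HarmonicTable,
    averaged_amplitude_spectrum,
    compare_agents_ttest,
    extract_harmonics,
    harmonic_response,
    harmonic_table_vs_saline,
    segment_pulses,
    snonl_vs_fundamental,
    snonl_vs_saline,
    summarize_replicates,
)
from ucachar.synthetic import SimulationConfig, simulate_scatter_acquisition


def _record(samples, fs=25.0, f0=2.25, starts=(0,)):
    return AcquisitionRecord(
        samples=np.asarray(samples, dtype=float),
        fs=fs, f0=f0, pulse_starts=np.asarray(starts, dtype=int),
    )


class TestSegmentPulses:
    def test_protocol_segmentation_93x225(self, noisy_cfg):
        rec = simulate_scatter_acquisition(noisy_cfg)
        segs = segment_pulses(rec, window_us=9.0)
        assert segs.shape == (93, 225)  # 9 us at 25 MHz

    def test_window_overrun_raises(self):
        rec = _record(np.zeros(200), starts=[0, 100])
        with pytest.raises(ValueError, match="overruns"):
            segment_pulses(rec, window_us=5.0)  # 125 samples > 100 spacing

    def test_zero_record_gives_zero_segments(self):
        rec = _record(np.zeros(10000), starts=[0, 5000])
        segs = segment_pulses(rec, window_us=9.0)
        assert segs.shape == (2, 225)
        assert not segs.any()

    def test_offset_shifts_window(self):
        samples = np.zeros(1000)
        samples[100:150] = 1.0
        rec = _record(samples, starts=[0])
        assert segment_pulses(rec, window_us=2.0, offset_us=4.0).sum() == 50.0
        assert segment_pulses(rec, window_us=2.0, offset_us=0.0).sum() == 0.0


class TestAveragedSpectrum:
    def test_identical_segments_equal_single(self, rng):
        seg = rng.normal(size=256)
        single = averaged_amplitude_spectrum(seg[None, :], fs=25.0)
        many = averaged_amplitude_spectrum(np.tile(seg, (7, 1)), fs=25.0)
        np.testing.assert_allclose(many.amplitude, single.amplitude)
        assert many.n_pulses_averaged == 7

    def test_hanning_line_shape_at_bin_center(self):
        # unit tone at bin j: adjacent bins carry exactly half the peak
        n, j, fs = 256, 30, 25.0
        tone = np.sin(2 * np.pi * j * np.arange(n) / n)
        spec = averaged_amplitude_spectrum(tone, window="hann", fs=fs)
        assert spec.amplitude[j] == pytest.approx(1.0, rel=1e-9)
        assert spec.amplitude[j - 1] / spec.amplitude[j] == pytest.approx(0.5, rel=1e-9)
        assert spec.amplitude[j + 1] / spec.amplitude[j] == pytest.approx(0.5, rel=1e-9)

    def test_zero_segments_zero_amplitude(self):
        spec = averaged_amplitude_spectrum(np.zeros((3, 64)), fs=25.0)
        assert not spec.amplitude.any()

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            averaged_amplitude_spectrum(np.empty((0, 64)), fs=25.0)

    def test_linearity_in_amplitude(self, rng):
        segs = rng.normal(size=(5, 128))
        a1 = averaged_amplitude_spectrum(segs, fs=25.0).amplitude
        a3 = averaged_amplitude_spectrum(3.0 * segs, fs=25.0).amplitude
        np.testing.assert_allclose(a3, 3.0 * a1, rtol=1e-12)


class TestExtractHarmonics:
    def test_synthetic_ratio_within_one_percent(self, clean_cfg):
        rec = simulate_scatter_acquisition(clean_cfg)
        table = harmonic_response(rec, [1, 2])
        assert table.value_at(2) / table.value_at(1) == pytest.approx(0.1, rel=0.01)

    def test_zero_halfwidth_reads_nearest_bin(self):
        spec = averaged_amplitude_spectrum(np.ones((1, 100)), fs=25.0)
        table = extract_harmonics(spec, f0=2.25, orders=[1], search_halfwidth=0.0)
        nearest = np.argmin(np.abs(spec.freqs - 2.25))
        assert table.value_at(1) == spec.amplitude[nearest]

    def test_nyquist_violation(self):
        spec = averaged_amplitude_spectrum(np.ones((1, 100)), fs=25.0)
        with pytest.raises(ValueError, match="Nyquist"):
            extract_harmonics(spec, f0=5.0, orders=[1, 3], search_halfwidth=0.1)

    def test_absent_subharmonic_reads_noise_floor(self, noisy_cfg):
        rec = simulate_scatter_acquisition(noisy_cfg)
        table = harmonic_response(rec, [0.5, 1])
        assert table.value_at(0.5) < 0.01 * table.value_at(1)

    def test_fundamental_statistic_exactly_zero(self, clean_cfg):
        rec = simulate_scatter_acquisition(clean_cfg)
        table = harmonic_response(rec, [0.5, 1, 2])
        assert table.snonl_fund_dB[list(table.orders).index(1.0)] == 0.0


class TestDbStatistics:
    @pytest.mark.parametrize(
        "a, ref, expected",
        [(1.0, 1.0, 0.0), (10.0, 1.0, 10.0), (2.0, 1.0, 10 * math.log10(2))],
    )
    def test_snonl_vs_saline(self, a, ref, expected):
        assert snonl_vs_saline(a, ref) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "a, a0, expected",
        [(1.0, 1.0, 0.0), (0.1, 1.0, -10.0), (0.5, 1.0, -10 * math.log10(2))],
    )
    def test_snonl_vs_fundamental(self, a, a0, expected):
        assert snonl_vs_fundamental(a, a0) == pytest.approx(expected, abs=1e-12)

    def test_20log10_convention_flag(self):
        assert snonl_vs_saline(2.0, 1.0, db_factor=20.0) == pytest.approx(6.0206, abs=1e-4)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            snonl_vs_saline(1.0, 0.0)
        with pytest.raises(ValueError):
            snonl_vs_fundamental(1.0, -1.0)

    def test_saline_table_fill(self):
        agent = HarmonicTable(f0=1.0, orders=[1, 2], amplitude=[2.0, 0.2])
        saline = HarmonicTable(f0=1.0, orders=[1, 2], amplitude=[1.0, 0.2])
        harmonic_table_vs_saline(agent, saline)
        np.testing.assert_allclose(
            agent.snonl_saline_dB, [10 * math.log10(2), 0.0], atol=1e-12
        )


def _table(values):
    return HarmonicTable(
        f0=1.0, orders=[1, 2], amplitude=[1.0, 0.1],
        snonl_fund_dB=np.asarray(values, dtype=float),
    )


class TestReplicateSummary:
    def test_identical_tables(self):
        summary = summarize_replicates([_table([0, -10])] * 5)
        np.testing.assert_allclose(summary.mean, [0, -10])
        np.testing.assert_allclose(summary.std, 0.0)

    def test_two_table_closed_form(self):
        summary = summarize_replicates([_table([0, -9]), _table([0, -11])])
        assert summary.mean[1] == pytest.approx(-10.0)
        assert summary.std[1] == pytest.approx(2 / math.sqrt(2))

    def test_sampling_distribution_of_mean(self, rng):
        mu, sigma, n = -10.0, 1.0, 15
        tables = [_table([0, rng.normal(mu, sigma)]) for _ in range(n)]
        summary = summarize_replicates(tables)
        assert abs(summary.mean[1] - mu) < 4 * sigma / math.sqrt(n)
        assert summary.n_replicates == n

    def test_mismatched_orders_rejected(self):
        other = HarmonicTable(f0=1.0, orders=[1, 3], amplitude=[1, 0.1],
                              snonl_fund_dB=np.array([0.0, -5.0]))
        with pytest.raises(ValueError, match="orders"):
            summarize_replicates([_table([0, -10]), other])


class TestAgentComparison:
    def test_identical_groups_p_one(self):
        p, sig = compare_agents_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)
        assert not sig

    def test_large_shift_significant(self):
        p, sig = compare_agents_ttest([1, 2, 3], [101, 102, 103])
        assert p < 0.001 and sig

    def test_zero_variance_identical_groups(self):
        p, _ = compare_agents_ttest([5.0, 5.0], [5.0, 5.0])
        assert p == 1.0

    def test_matches_exhaustive_permutation_oracle(self, rng):
        a = rng.normal(0.0, 1.0, 5)
        b = rng.normal(1.5, 1.0, 5)
        p_t, _ = compare_agents_ttest(a, b)
        # exact permutation distribution of the pooled-t statistic
        pooled = np.concatenate([a, b])
        idx = range(pooled.size)

        def tstat(x, y):
            sp = np.sqrt(((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
                         / (x.size + y.size - 2))
            return (x.mean() - y.mean()) / (sp * np.sqrt(1 / x.size + 1 / y.size))

        t_obs = abs(tstat(a, b))
        count = 0
        total = 0
        for combo in itertools.combinations(idx, 5):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(combo)] = True
            if abs(tstat(pooled[mask], pooled[~mask])) >= t_obs - 1e-12:
                count += 1
            total += 1
        p_perm = count / total
        assert abs(p_t - p_perm) <= 0.05  # within the 252-split resolution
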