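"""Wavelet-packet decomposition and feature-extractor contracts."""

import math

import numpy as np
import pytest
import pywt
from hypothesis import given, strategies as st

from wafecg import ECGSegment, WaveletConfig, extract_afe, extract_entropy_features, extract_wpap
from wafecg import feature_statistics, percentage_energy, wpt_decompose
from wafecg.exceptions import DecompositionError, DegenerateSignalError, IncompatibleFeaturesError
from wafecg.features import FeatureVector, _log_energy_entropy, _shannon_entropy, _sure_entropy
from wafecg.features import features_from_csv, features_to_csv
from wafecg.synthetic import PRESETS, synth_segment


def _rand_seg(seed=0, n=2500, fs=250.0):
    rng = np.random.default_rng(seed)
    return ECGSegment(rng.standard_normal(n), fs=fs)


def _wp_reference_subsignals(x, cfg):
    """Independent per-node reconstruction via pywt.WaveletPacket objects
    (a different code path from the library's idwt upsampling chain)."""
    wp = pywt.WaveletPacket(x, cfg.wavelet_name, mode=cfg.boundary_mode, maxlevel=cfg.level)
    order = "freq" if cfg.node_order == "frequency" else "natural"
    subs = []
    for node in wp.get_level(cfg.level, order=order):
        empty = pywt.WaveletPacket(None, cfg.wavelet_name, mode=cfg.boundary_mode, maxlevel=cfg.level)
        empty[node.path] = node.data
        subs.append(empty.reconstruct(update=False)[: len(x)])
    return np.array(subs)


class TestDecomposition:
    def test_terminal_subsignals_sum_to_input(self, nsr_segment, wcfg):
        subs = wpt_decompose(nsr_segment, wcfg)
        recon = subs.subsignals.sum(axis=0)
        assert np.max(np.abs(recon - nsr_segment.samples[: subs.length])) < 1e-8

    def test_energy_is_conserved(self, nsr_segment, wcfg):
        subs = wpt_decompose(nsr_segment, wcfg)
        e_in = np.sum(nsr_segment.samples[: subs.length] ** 2)
        e_sub = np.sum(subs.subsignals**2)
        assert abs(e_sub - e_in) / e_in < 1e-6
        assert abs(subs.total_energy - e_in) / e_in < 1e-6

    def test_reconstruction_matches_independent_route(self, wcfg):
        seg = _rand_seg(3, n=2496)
        subs = wpt_decompose(seg, wcfg)
        ref = _wp_reference_subsignals(seg.samples, wcfg)
        assert np.max(np.abs(subs.subsignals - ref)) < 1e-10

    def test_analyzed_prefix_is_largest_multiple_of_block(self, wcfg):
        subs = wpt_decompose(_rand_seg(1, n=2500), wcfg)
        assert subs.length == 2496
        assert subs.n_nodes == 32

    def test_too_short_segment_raises(self, wcfg):
        with pytest.raises(DecompositionError):
            wpt_decompose(ECGSegment(np.ones(16), fs=250.0), wcfg)

    def test_pure_tone_concentrates_in_its_subband(self):
        # frequency-ordered level-5 nodes at fs=250 cover bands of width
        # 125/32 = 3.906 Hz; a 10 Hz tone belongs to node index 2
        cfg = WaveletConfig(node_order="frequency")
        t = np.arange(2496) / 250.0
        seg = ECGSegment(np.sin(2 * np.pi * 10.0 * t), fs=250.0)
        subs = wpt_decompose(seg, cfg)
        energies = np.sum(subs.subsignals**2, axis=1)
        share = energies[1:4].sum() / energies.sum()
        assert share >= 0.90


class TestWAFE:
    def test_percentage_energy_sums_to_100_per_frame(self, chf_segment, wcfg):
        subs = wpt_decompose(chf_segment, wcfg)
        for z in range(1, wcfg.n_frames + 1):
            pe = percentage_energy(subs, z)
            assert pe.min() >= 0
            assert abs(pe.sum() - 100.0) < 1e-6

    def test_frame_index_bounds(self, nsr_segment, wcfg):
        subs = wpt_decompose(nsr_segment, wcfg)
        with pytest.raises(DecompositionError):
            percentage_energy(subs, 0)
        with pytest.raises(DecompositionError):
            percentage_energy(subs, wcfg.n_frames + 1)

    @pytest.mark.parametrize("z", [1, 2, 4, 5, 10])
    def test_afe_sum_and_length_for_all_framings(self, nsr_segment, z):
        cfg = WaveletConfig(n_frames=z)
        fv = extract_afe(nsr_segment, cfg)
        assert len(fv.values) == 32
        assert fv.values.min() >= 0
        assert abs(fv.values.sum() - 100.0) < 1e-6

    def test_single_frame_equals_whole_segment_percentages(self, chf_segment):
        cfg = WaveletConfig(n_frames=1)
        fv = extract_afe(chf_segment, cfg)
        subs = wpt_decompose(chf_segment, cfg)
        direct = 100.0 * np.array([np.sum(c**2) for c in subs.coefficients]) / subs.total_energy
        np.testing.assert_allclose(fv.values, direct, atol=1e-6)

    def test_amplitude_scale_invariance(self, nsr_segment, wcfg):
        base = extract_afe(nsr_segment, wcfg).values
        for scale in (1e-3, 0.1, 10.0, 1e3):
            scaled = ECGSegment(nsr_segment.samples * scale, fs=nsr_segment.fs)
            assert np.max(np.abs(extract_afe(scaled, wcfg).values - base)) < 1e-9

    def test_two_identical_halves_give_frame_vector(self, wcfg):
        half = _rand_seg(17, n=1248).samples
        seg = ECGSegment(np.concatenate([half, half]), fs=250.0)
        cfg = WaveletConfig(n_frames=2)
        fv = extract_afe(seg, cfg)
        subs = wpt_decompose(seg, cfg)
        np.testing.assert_allclose(fv.values, percentage_energy(subs, 1), atol=1e-6)
        np.testing.assert_allclose(fv.values, percentage_energy(subs, 2), atol=1e-6)

    def test_matches_straight_line_two_pass_oracle(self, wcfg):
        seg = _rand_seg(23, n=2500)
        ref_subs = _wp_reference_subsignals(seg.samples[:2496], wcfg)
        Z = wcfg.n_frames
        flen = 2496 // Z
        frames = []
        for z in range(Z):
            e = np.sum(ref_subs[:, z * flen : (z + 1) * flen] ** 2, axis=1)
            frames.append(100.0 * e / e.sum())
        oracle = np.mean(frames, axis=0)
        fv = extract_afe(seg, wcfg)
        np.testing.assert_allclose(fv.values, oracle, atol=1e-9)

    @given(st.integers(0, 10_000), st.sampled_from([1, 2, 4, 5]), st.floats(1e-3, 1e3))
    def test_property_nonneg_sum100_scale_invariant(self, seed, z, scale):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 80)) * 32
        x = rng.standard_normal(n)
        cfg = WaveletConfig(n_frames=z)
        a = extract_afe(ECGSegment(x, fs=250.0), cfg).values
        b = extract_afe(ECGSegment(scale * x, fs=250.0), cfg).values
        assert a.min() >= 0
        assert abs(a.sum() - 100.0) < 1e-6
        assert np.max(np.abs(a - b)) < 1e-9


class TestEntropies:
    def test_one_hot_block_has_zero_shannon_entropy(self):
        c = np.zeros(32)
        c[7] = 3.5
        assert _shannon_entropy(c) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_block_attains_maximum_entropy(self):
        for m in (4, 16, 50):
            c = np.full(m, 0.7)
            assert _shannon_entropy(c) == pytest.approx(math.log(m), rel=1e-12)

    def test_entropy_functions_match_direct_summation(self):
        rng = np.random.default_rng(0)
        c = rng.standard_normal(64)
        p = c**2 / np.sum(c**2)
        assert _shannon_entropy(c) == pytest.approx(-np.sum(p * np.log(p)), abs=1e-9)
        assert _log_energy_entropy(c) == pytest.approx(
            np.sum(np.log(np.maximum(c**2, 1e-12))), abs=1e-9
        )
        tau2 = 2 * math.log(64 * math.log2(64))
        assert _sure_entropy(c) == pytest.approx(np.sum(np.minimum(c**2, tau2)), abs=1e-9)

    def test_segment_level_extraction_matches_per_node_oracle(self, nsr_segment, wcfg):
        fv = extract_entropy_features(nsr_segment, wcfg, "shannon")
        subs = wpt_decompose(nsr_segment, wcfg)
        Z = wcfg.n_frames
        oracle = []
        for c in subs.coefficients:
            flen = len(c) // Z
            oracle.append(np.mean([_shannon_entropy(c[z * flen : (z + 1) * flen]) for z in range(Z)]))
        np.testing.assert_allclose(fv.values, oracle, atol=1e-12)
        assert fv.extractor == "WPSE"

    def test_unknown_kind_rejected(self, nsr_segment):
        with pytest.raises(IncompatibleFeaturesError):
            extract_entropy_features(nsr_segment, kind="renyi")


class TestWPAP:
    def test_zero_signal_is_degenerate(self, wcfg):
        with pytest.raises((DegenerateSignalError, DecompositionError)):
            extract_wpap(ECGSegment(np.zeros(2496), fs=250.0), wcfg)

    def test_quadratic_scaling(self, nsr_segment, wcfg):
        base = extract_wpap(nsr_segment, wcfg).values
        doubled = extract_wpap(
            ECGSegment(2 * nsr_segment.samples, fs=nsr_segment.fs), wcfg
        ).values
        np.testing.assert_allclose(doubled, 4 * base, rtol=1e-9)

    def test_white_noise_is_roughly_flat_across_nodes(self, wcfg):
        # single-segment node estimates fluctuate (chi-squared with few
        # effective dof); average a small Monte-Carlo ensemble
        vals = np.mean(
            [extract_wpap(_rand_seg(99 + i, n=2500), wcfg).values for i in range(20)],
            axis=0,
        )
        assert vals.max() / vals.min() < 3.0


class TestStatistics:
    def test_constant_vector(self, wcfg):
        fv = FeatureVector(np.full(32, 3.125), "WAFE", wcfg)
        s = feature_statistics(fv)
        assert s.std == 0 and s.var == 0
        assert s.median == s.max == pytest.approx(3.125)

    def test_one_hot_vector(self, wcfg):
        v = np.zeros(32)
        v[-1] = 100.0
        s = feature_statistics(FeatureVector(v, "WAFE", wcfg))
        assert s.max == 100.0 and s.median == 0.0

    def test_matches_textbook_formulas(self, wcfg):
        rng = np.random.default_rng(12)
        v = rng.uniform(0, 10, 32)
        s = feature_statistics(FeatureVector(v, "WAFE", wcfg))
        mean = v.sum() / 32
        var = np.sum((v - mean) ** 2) / 32
        assert s.var == pytest.approx(var, rel=1e-12)
        assert s.std == pytest.approx(math.sqrt(var), rel=1e-12)
        assert s.var == pytest.approx(s.std**2, rel=1e-12)
        assert s.max >= s.median


class TestSerialization:
    def test_csv_round_trip(self, tmp_path, small_dataset, wcfg):
        feats = [extract_afe(s, wcfg) for s in small_dataset["NSR"][:3]]
        path = tmp_path / "feats.csv"
        features_to_csv(feats, path)
        back = features_from_csv(path)
        assert len(back) == 3
        for a, b in zip(feats, back):
            np.testing.assert_array_equal(a.values, b.values)
            assert a.extractor == b.extractor and a.config == b.config


class TestSeparability:
    def test_within_class_distance_below_between_class(self, small_dataset, wcfg):
        nsr = np.array([extract_afe(s, wcfg).values for s in small_dataset["NSR"]])
        chf = np.array([extract_afe(s, wcfg).values for s in small_dataset["CHF"]])

        def mean_pairwise(a, b):
            return np.mean([np.linalg.norm(x - y) for x in a for y in b if x is not y])

        within = 0.5 * (mean_pairwise(nsr, nsr) + mean_pairwise(chf, chf))
        between = mean_pairwise(nsr, chf)
        assert between > 2.0 * within
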