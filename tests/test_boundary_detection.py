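import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pcgseg.audio_io import AudioSignal
from pcgseg.boundary_detection import (BoundarySet, EnvelopeSignal,
                                       EnvelopeStage, MorphologyParams,
                                       ThresholdParams, adaptive_threshold,
                                       detect_boundaries, energy_filter,
                                       extract_candidate_boundaries,
                                       morphological_closing,
                                       morphological_opening)


def brute_force_closing(x, q):
    """O(N*Q) sliding max then min (reflected element), edge-shrinking windows."""
    return _slide(_slide(x, q, max, False), q, min, True)


def brute_force_opening(x, q):
    return _slide(_slide(x, q, min, False), q, max, True)


def _slide(x, q, agg, reflected):
    n = len(x)
    left = (q - 1) // 2 if reflected else q // 2
    right = q - 1 - left
    return np.array([agg(x[max(0, i - left): min(n, i + right + 1)])
                     for i in range(n)])


class TestMorphology:
    def test_closing_constant_unchanged(self):
        x = np.full(10, 0.7)
        assert np.allclose(morphological_closing(x, 3), x)

    def test_closing_fills_valley(self):
        out = morphological_closing(np.array([0, 1, 0, 1, 0.0]), 3)
        assert np.allclose(out, 1.0)

    def test_opening_removes_spike(self):
        out = morphological_opening(np.array([0, 0, 1, 0, 0.0]), 3)
        assert np.allclose(out, 0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), n=st.integers(5, 60), q=st.integers(1, 12))
    def test_matches_brute_force_oracles(self, seed, n, q):
        x = np.abs(np.random.default_rng(seed).standard_normal(n))
        assert np.array_equal(morphological_closing(x, q), brute_force_closing(x, q))
        assert np.array_equal(morphological_opening(x, q), brute_force_opening(x, q))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), q=st.integers(1, 15))
    def test_extensivity_and_idempotence(self, seed, q):
        x = np.abs(np.random.default_rng(seed).standard_normal(50))
        closed = morphological_closing(x, q)
        opened = morphological_opening(x, q)
        assert np.all(closed >= x - 1e-12)          # closing is extensive
        assert np.all(opened <= x + 1e-12)          # opening is anti-extensive
        assert np.allclose(morphological_closing(closed, q), closed)
        assert np.allclose(morphological_opening(opened, q), opened)

    def test_separated_bursts_not_merged(self):
        """Two humps >= 200 samples apart survive Q=30 closing as two runs."""
        x = np.zeros(1000)
        x[100:200] = 1.0
        x[450:550] = 1.0  # gap of 250 samples
        closed = morphological_closing(x, 30)
        interior = closed[220:430]
        assert np.all(interior == 0)

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            morphological_closing(np.ones(4), 0)


class TestAdaptiveThreshold:
    def test_hand_example(self):
        """mu=0.4, theta_A=0.8*sqrt(0.14)~0.2993, theta=min(.,0.025)=0.025."""
        env = EnvelopeSignal(np.array([0, 0.5, 1.0, 0.5, 0]), 2000.0,
                             EnvelopeStage.CLOSED)
        out, theta, theta_a, mu = adaptive_threshold(env)
        assert mu == pytest.approx(0.4)
        assert theta_a == pytest.approx(0.8 * np.sqrt(0.14))
        assert theta == pytest.approx(0.025)
        assert np.array_equal(out.values, env.values)  # nothing below 0.025

    def test_small_plateau_zeroed(self):
        values = np.array([0, 0.01, 0.01, 0.5, 1.0, 0.5, 0, 0])
        env = EnvelopeSignal(values, 2000.0, EnvelopeStage.CLOSED)
        out, *_ = adaptive_threshold(env)
        assert np.all(out.values[1:3] == 0)

    def test_degenerate_constant_envelope(self):
        env = EnvelopeSignal(np.ones(6), 2000.0, EnvelopeStage.CLOSED)
        out, theta, theta_a, mu = adaptive_threshold(env)
        assert theta == 0.0  # std is zero, so the adaptive branch wins
        assert np.array_equal(out.values, env.values)


class TestCandidateExtraction:
    def test_hand_example(self):
        env = EnvelopeSignal(np.array([0, 0, 0.3, 0.4, 0, 0, 0.2, 0]), 2000.0,
                             EnvelopeStage.OPENED)
        bs = extract_candidate_boundaries(env)
        assert bs.onsets.tolist() == [1, 5]
        assert bs.offsets.tolist() == [4, 7]

    def test_all_zero(self):
        env = EnvelopeSignal(np.zeros(10), 2000.0, EnvelopeStage.OPENED)
        assert extract_candidate_boundaries(env).n_pairs == 0

    def test_edge_runs_use_edge_indices(self):
        env = EnvelopeSignal(np.array([0.5, 0.5, 0, 0, 0.1, 0.2]), 2000.0,
                             EnvelopeStage.OPENED)
        bs = extract_candidate_boundaries(env)
        assert bs.onsets.tolist() == [0, 3]
        assert bs.offsets.tolist() == [2, 5]


class TestEnergyFilter:
    def test_hand_example(self):
        """E_0 = 0.25 kept (tie), E_1 = 0.04 removed and zeroed."""
        values = np.array([0, 0, 0.3, 0.4, 0, 0, 0.2, 0])
        env = EnvelopeSignal(values, 2000.0, EnvelopeStage.OPENED)
        bs = extract_candidate_boundaries(env)
        assert bs.energies.tolist() == pytest.approx([0.25, 0.04])
        out_env, out_bs = energy_filter(env, bs, 0.25)
        assert out_bs.onsets.tolist() == [1]
        assert out_bs.offsets.tolist() == [4]
        assert np.all(out_env.values[5:] == 0)

    def test_all_pairs_survive(self):
        values = np.array([0, 0.9, 0.9, 0, 0, 0.8, 0.8, 0])
        env = EnvelopeSignal(values, 2000.0, EnvelopeStage.OPENED)
        bs = extract_candidate_boundaries(env)
        _, out_bs = energy_filter(env, bs, 0.25)
        assert out_bs.n_pairs == 2

    def test_all_pairs_removed(self):
        values = np.array([0, 0.1, 0, 0, 0.1, 0.0])
        env = EnvelopeSignal(values, 2000.0, EnvelopeStage.OPENED)
        bs = extract_candidate_boundaries(env)
        out_env, out_bs = energy_filter(env, bs, 0.25)
        assert out_bs.n_pairs == 0
        assert np.all(out_env.values == 0)


class TestBoundarySetInvariants:
    def test_strict_interleaving_enforced(self):
        with pytest.raises(ValueError):
            BoundarySet(onsets=np.array([0, 3]), offsets=np.array([3, 6]),
                        energies=np.array([1.0, 1.0]))


class TestDetectBoundaries:
    def test_clean_train_six_pairs_within_20ms(self):
        from pcgseg.murmur_elimination import eliminate_murmurs
        from pcgseg.synthetic import generate, preset_catalog
        sig, gt = generate(preset_catalog()["normal"])
        filtered, _ = eliminate_murmurs(sig)
        bs, env, diag = detect_boundaries(filtered)
        assert bs.n_pairs == 6
        truth_onsets = np.array([a.onset_sample for a in gt.annotations])
        assert np.all(np.abs(bs.onsets - truth_onsets) <= 40)  # 20 ms at 2 kHz

    def test_click_removed(self):
        from pcgseg.murmur_elimination import eliminate_murmurs
        from pcgseg.synthetic import generate, preset_catalog
        sig, gt = generate(preset_catalog()["click"])
        filtered, _ = eliminate_murmurs(sig)
        bs, _, _ = detect_boundaries(filtered)
        assert bs.n_pairs == 6  # 3 cycles x (S1, S2); clicks rejected

    def test_silence_yields_no_pairs(self):
        bs, env, _ = detect_boundaries(AudioSignal(np.zeros(1000), 2000.0))
        assert bs.n_pairs == 0

    def test_interleaving_holds_on_noise(self, rng):
        sig = AudioSignal(rng.standard_normal(4000) * 0.3, 2000.0)
        bs, _, _ = detect_boundaries(sig)
        if bs.n_pairs:
            merged = np.empty(2 * bs.n_pairs, dtype=int)
            merged[0::2] = bs.onsets
            merged[1::2] = bs.offsets
            assert np.all(np.diff(merged) > 0)
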