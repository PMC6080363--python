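import numpy as np
import pytest

from pcgseg.audio_io import AudioSignal
from pcgseg.boundary_detection import BoundarySet
from pcgseg.cardiac_cycle import CycleEstimate
from pcgseg.component_identification import (InstantaneousFrequency,
                                             TimeFrequencyMatrix,
                                             build_segmentation,
                                             component_avg_frequencies,
                                             group_into_beats,
                                             instantaneous_frequency,
                                             instantaneous_frequency_from_signal,
                                             recognize_components,
                                             stockwell_transform)


def stockwell_brute_force(x, fs):
    """Literal double-sum S-transform (row 0 = signal mean), O(N^3) oracle."""
    n = len(x)
    H = np.fft.fft(x)
    S = np.empty((n, n), dtype=complex)
    S[0, :] = np.mean(x)
    for row in range(1, n):
        gauss = np.exp(-2 * np.pi**2 * np.arange(n) ** 2 / row**2)
        for j in range(n):
            phases = np.exp(2j * np.pi * np.arange(n) * j / n)
            S[row, j] = np.sum(H[(np.arange(n) + row) % n] * gauss * phases)
    return S


def _bs(onsets, offsets):
    return BoundarySet(onsets=np.array(onsets), offsets=np.array(offsets),
                       energies=np.ones(len(onsets)))


def _cycle(samples, fs=2000.0):
    return CycleEstimate(avg_cycle_samples=samples, fs=fs,
                         peak_lags=np.array([int(samples)]), n_intervals=1)


class TestStockwellTransform:
    def test_zero_signal(self):
        tf = stockwell_transform(AudioSignal(np.zeros(16), 2000.0))
        assert np.all(tf.S == 0)

    @pytest.mark.parametrize("n", [8, 16, 32, 64])
    def test_matches_brute_force(self, n):
        x = np.random.default_rng(n).standard_normal(n)
        fs = 2000.0
        ref = stockwell_brute_force(x, fs)
        tf = stockwell_transform(AudioSignal(x, fs), max_freq_hz=fs / 4)
        rows = tf.S.shape[0]
        assert np.max(np.abs(tf.S - ref[:rows])) < 1e-10

    def test_pure_tone_localized(self):
        fs, n, f0 = 2000.0, 256, 250.0
        x = np.sin(2 * np.pi * f0 * np.arange(n) / fs)
        tf = stockwell_transform(AudioSignal(x, fs), max_freq_hz=300.0)
        mod = tf.modulus
        m0 = int(round(f0 * n / fs))  # DFT row index of the tone
        interior = mod[:, n // 4: 3 * n // 4]
        assert np.all(np.argmax(interior, axis=0) == m0)

    def test_restricted_rows_frequency_axis(self):
        tf = stockwell_transform(AudioSignal(np.ones(64), 2000.0),
                                 max_freq_hz=100.0)
        assert tf.freq_hz[0] == 0.0
        assert np.all(np.diff(tf.freq_hz) > 0)
        assert tf.freq_hz[-1] <= 100.0


class TestInstantaneousFrequency:
    def test_single_row_mass(self):
        S = np.zeros((3, 4), dtype=complex)
        S[2, :] = 1.0
        tf = TimeFrequencyMatrix(S=S, freq_hz=np.array([0.0, 50.0, 100.0]),
                                 fs=2000.0)
        inst = instantaneous_frequency(tf)
        assert np.allclose(inst.values_hz, 100.0)

    def test_weighted_mean_by_hand(self):
        S = np.ones((2, 3), dtype=complex)
        tf = TimeFrequencyMatrix(S=S, freq_hz=np.array([0.0, 100.0]), fs=2000.0)
        assert np.allclose(instantaneous_frequency(tf).values_hz, 50.0)

    def test_bounded_by_frequency_axis(self, rng):
        S = (rng.standard_normal((6, 10)) + 1j * rng.standard_normal((6, 10)))
        freq = np.arange(6) * 10.0
        inst = instantaneous_frequency(TimeFrequencyMatrix(S, freq, 2000.0))
        assert np.all(inst.values_hz >= 0.0)
        assert np.all(inst.values_hz <= 50.0)

    def test_pure_tone_within_one_bin(self):
        """f_H of a tone lands within one bin width of the tone's (halved)
        frequency for interior samples."""
        fs, n, f0 = 2000.0, 512, 100.0
        x = np.sin(2 * np.pi * f0 * np.arange(n) / fs)
        inst = instantaneous_frequency_from_signal(AudioSignal(x, fs), 300.0)
        bin_width = fs / (2 * n)
        interior = inst.values_hz[n // 4: 3 * n // 4]
        assert np.all(np.abs(interior - f0 / 2) <= bin_width)

    def test_streaming_equals_matrix_route(self, rng):
        x = rng.standard_normal(128)
        sig = AudioSignal(x, 2000.0)
        a = instantaneous_frequency(stockwell_transform(sig, 300.0)).values_hz
        b = instantaneous_frequency_from_signal(sig, 300.0).values_hz
        assert np.allclose(a, b)


class TestComponentAverages:
    def test_constant_frequency_span(self):
        inst = InstantaneousFrequency(values_hz=np.full(100, 60.0), fs=2000.0)
        out = component_avg_frequencies(inst, _bs([10], [40]))
        assert out[0] == pytest.approx(60.0)

    def test_gallop_sound_has_lowest_average(self):
        """In a beat with S1 (100 Hz), S2 (120 Hz) and S4 (35 Hz), the S4
        span's average instantaneous frequency is strictly lowest."""
        from pcgseg.synthetic import generate, preset_catalog
        sig, gt = generate(preset_catalog()["s4"])
        inst = instantaneous_frequency_from_signal(sig, 300.0)
        bs = _bs([a.onset_sample for a in gt.annotations],
                 [a.offset_sample for a in gt.annotations])
        avg = component_avg_frequencies(inst, bs)
        labels = [a.label for a in gt.annotations]
        s4 = [f for f, lab in zip(avg, labels) if lab == "S4"]
        rest = [f for f, lab in zip(avg, labels) if lab != "S4"]
        assert max(s4) < min(rest)

    def test_minimal_span(self):
        inst = InstantaneousFrequency(values_hz=np.arange(10.0), fs=2000.0)
        out = component_avg_frequencies(inst, _bs([4], [5]))
        assert out[0] == pytest.approx(4.5)


class TestGroupIntoBeats:
    def test_three_two_component_beats(self):
        c = 1600
        onsets = [0, int(0.3 * c), c, int(1.3 * c), 2 * c, int(2.3 * c)]
        bs = _bs(onsets, [o + 100 for o in onsets])
        beats = group_into_beats(bs, _cycle(c))
        assert [len(b) for b in beats] == [2, 2, 2]

    def test_lonely_component_flagged_unknown(self):
        bs = _bs([0], [100])
        beats = group_into_beats(bs, _cycle(1600))
        labeled = recognize_components(beats, np.array([100.0]), bs, 2000.0)
        assert labeled[0].label == "unknown"

    def test_overfull_beat_flagged_unknown(self):
        onsets = [0, 200, 400, 600, 800]
        bs = _bs(onsets, [o + 100 for o in onsets])
        beats = group_into_beats(bs, _cycle(1600))
        labeled = recognize_components(beats, np.full(5, 100.0), bs, 2000.0)
        assert all(c.label == "unknown" for c in labeled)


class TestRecognizeComponents:
    def test_two_component_rule(self):
        """Short intra-beat gap (0.3 s) vs long inter-beat gap: S1 first."""
        fs = 2000.0
        onsets = [0, 600, 1600, 2200]
        bs = _bs(onsets, [o + 200 for o in onsets])
        beats = [[0, 1], [2, 3]]
        labeled = recognize_components(beats, np.full(4, 100.0), bs, fs)
        assert [c.label for c in labeled] == ["S1", "S2", "S1", "S2"]

    def test_two_component_rule_s2_first(self):
        """Recording starts mid-cycle: intra gap longer than inter gap."""
        fs = 2000.0
        onsets = [0, 1000, 1600, 2600]
        bs = _bs(onsets, [o + 200 for o in onsets])
        beats = [[0, 1], [2, 3]]
        labeled = recognize_components(beats, np.full(4, 100.0), bs, fs)
        assert [c.label for c in labeled][:2] == ["S2", "S1"]

    def test_three_component_gallop_close_to_s2_is_s3(self):
        fs = 2000.0
        # S1 at 0, S2 at 600, gallop at 1100 (gap 0.12 s to S2), next S1 at 2000
        onsets = [0, 600, 1100, 2000, 2600, 3100, 4000, 4600, 5100]
        offsets = [200, 840, 1210, 2200, 2840, 3210, 4200, 4840, 5110]
        bs = _bs(onsets, offsets)
        freqs = np.array([100, 120, 40.0] * 3)
        beats = [[0, 1, 2], [3, 4, 5], [6, 7, 8]]
        labeled = recognize_components(beats, freqs, bs, fs)
        assert [c.label for c in labeled[:3]] == ["S1", "S2", "S3"]

    def test_three_component_verbatim_rule_flips(self):
        fs = 2000.0
        onsets = [0, 600, 1100, 2000, 2600, 3100, 4000, 4600, 5100]
        offsets = [200, 840, 1210, 2200, 2840, 3210, 4200, 4840, 5110]
        bs = _bs(onsets, offsets)
        freqs = np.array([100, 120, 40.0] * 3)
        beats = [[0, 1, 2], [3, 4, 5], [6, 7, 8]]
        labeled = recognize_components(beats, freqs, bs, fs,
                                       s3s4_rule="verbatim")
        assert labeled[2].label == "S4"

    def test_four_component_order(self):
        fs = 2000.0
        onsets = [0, 600, 1100, 1360, 1600, 2200, 2700, 2960]
        offsets = [o + 150 for o in onsets]
        bs = _bs(onsets, offsets)
        freqs = np.array([100, 120, 45, 35.0] * 2)
        beats = [[0, 1, 2, 3], [4, 5, 6, 7]]
        labeled = recognize_components(beats, freqs, bs, fs)
        assert [c.label for c in labeled[:4]] == ["S1", "S2", "S3", "S4"]


class TestBuildSegmentation:
    def test_interval_names_two_component(self):
        fs = 2000.0
        from pcgseg.component_identification import LabeledComponent
        comps = [
            LabeledComponent("S1", 0, 0, 0, 200, 100.0),
            LabeledComponent("S2", 0, 1, 600, 800, 120.0),
            LabeledComponent("S1", 1, 0, 1600, 1800, 100.0),
        ]
        seg = build_segmentation(comps, fs)
        assert [iv["name"] for iv in seg.intervals] == ["S1S2", "S2S1"]
        assert seg.intervals[0]["duration_s"] == pytest.approx(0.2)

    def test_unknown_components_excluded(self):
        from pcgseg.component_identification import LabeledComponent
        comps = [
            LabeledComponent("S1", 0, 0, 0, 200, 100.0),
            LabeledComponent("unknown", 0, 1, 600, 800, 120.0),
            LabeledComponent("S1", 1, 0, 1600, 1800, 100.0),
        ]
        seg = build_segmentation(comps, 2000.0)
        assert seg.intervals == []
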