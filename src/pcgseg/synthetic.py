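"""Ground-truthed synthetic phonocardiograms.

A heart sound component is modelled as a Gaussian-windowed sinusoid: a
transient tone burst whose centre frequency and duration follow the
physiology — S1/S2 around 80-150 Hz lasting ~100 ms, the S3/S4 gallop
sounds at 20-70 Hz lasting ~50 ms, with inter-component gaps of at least
100 ms inside a beat.  Murmurs are band-passed white noise confined to
the systolic or diastolic window (>150 Hz, noise-like), clicks are very
short high-frequency bursts, and optional white noise and per-cycle
timing jitter perturb the clean train.  Every generated recording comes
with exact ground truth: component annotations, the component/murmur
region mask for SMR, and the true cycle length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .audio_io import AudioSignal, Annotation
from .metrics import RegionMask


@dataclass(frozen=True)
class ComponentSpec:
    """One component per cycle: where it starts and what it sounds like."""

    label: str
    center_freq_hz: float
    duration_s: float
    amplitude: float
    offset_in_cycle_s: float


@dataclass(frozen=True)
class MurmurSpec:
    """Band-limited noise filling the systolic or diastolic gap."""

    band_lo_hz: float = 150.0
    band_hi_hz: float = 450.0
    window: str = "systolic"    # "systolic" (S1->S2) or "diastolic" (S2->next S1)
    amplitude: float = 0.15     # peak amplitude relative to S1's 1.0

    def __post_init__(self):
        if self.window not in ("systolic", "diastolic"):
            raise ValueError("murmur window must be 'systolic' or 'diastolic'")
        if not 0 < self.band_lo_hz < self.band_hi_hz:
            raise ValueError("murmur band must satisfy 0 < lo < hi")


@dataclass(frozen=True)
class ClickSpec:
    """A brief transient artifact inside each cycle."""

    offset_in_cycle_s: float = 0.2
    duration_s: float = 0.01
    center_freq_hz: float = 300.0
    amplitude: float = 0.12


# per-cycle component layout defaults; inter-component gaps respect the
# timing priors S1S2 < S2S1, S2S3 < S3S1, S2S4 > S4S1
S1 = ComponentSpec("S1", center_freq_hz=100.0, duration_s=0.10,
                   amplitude=1.0, offset_in_cycle_s=0.00)
S2 = ComponentSpec("S2", center_freq_hz=120.0, duration_s=0.10,
                   amplitude=0.8, offset_in_cycle_s=0.30)
S3 = ComponentSpec("S3", center_freq_hz=45.0, duration_s=0.05,
                   amplitude=0.40, offset_in_cycle_s=0.55)
S4 = ComponentSpec("S4", center_freq_hz=35.0, duration_s=0.05,
                   amplitude=0.35, offset_in_cycle_s=0.68)


@dataclass(frozen=True)
class SynthConfig:
    fs: float = 2000.0
    n_cycles: int = 3
    cycle_s: float = 0.8
    components: tuple[ComponentSpec, ...] = (S1, S2)
    murmur: MurmurSpec | None = None
    click: ClickSpec | None = None
    noise_std: float = 0.0
    timing_jitter_frac: float = 0.0
    seed: int = 0

    def __post_init__(self):
        spans = sorted((c.offset_in_cycle_s, c.offset_in_cycle_s + c.duration_s)
                       for c in self.components)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 < b1:
                raise ValueError("component spans within a cycle overlap")
        if spans and spans[-1][1] > self.cycle_s:
            raise ValueError("component extends past the cycle length")


@dataclass(frozen=True)
class GroundTruth:
    annotations: list[Annotation]
    region_mask: RegionMask
    true_cycle_s: float


def make_component(center_freq_hz: float, duration_s: float, amplitude: float,
                   fs: float) -> np.ndarray:
    """Gaussian-windowed sinusoid lasting ``duration_s``.

    The window standard deviation is duration/4 (span edges at 2 sigma,
    about -17 dB), so the sound keeps substantial amplitude across most of
    its nominal duration the way auscultated components do, rather than
    being a narrow blip.  Outside the span the envelope is exactly zero;
    the -40 dB envelope crossing therefore coincides with the span edges,
    which serve as the reproducible ground-truth boundaries.
    """
    n = int(round(duration_s * fs))
    if n < 8:
        raise ValueError("component too short: need at least 8 samples")
    t = (np.arange(n) - (n - 1) / 2) / fs
    sigma = duration_s / 4.0
    window = np.exp(-(t ** 2) / (2.0 * sigma ** 2))
    tone = np.sin(2.0 * np.pi * center_freq_hz * (np.arange(n) / fs)) * window
    if amplitude == 0 or np.max(np.abs(tone)) == 0:
        return np.zeros(n)
    return amplitude * tone / np.max(np.abs(tone))


def _bandpassed_noise(n: int, lo: float, hi: float, fs: float,
                      rng: np.random.Generator) -> np.ndarray:
    hi = min(hi, 0.995 * fs / 2.0)
    sos = butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    noise = sosfiltfilt(sos, rng.standard_normal(n + 200))[100:-100]
    peak = np.max(np.abs(noise))
    return noise / peak if peak > 0 else noise


def generate(config: SynthConfig) -> tuple[AudioSignal, GroundTruth]:
    """Render a recording plus exact ground truth; deterministic per seed."""
    fs = config.fs
    rng = np.random.default_rng(config.seed)

    # per-cycle start times, optionally jittered cycle by cycle
    starts = [0.0]
    for _ in range(1, config.n_cycles):
        jitter = 1.0 + config.timing_jitter_frac * rng.uniform(-1.0, 1.0)
        starts.append(starts[-1] + config.cycle_s * jitter)
    total_s = starts[-1] + config.cycle_s
    n_total = int(round(total_s * fs)) + 1
    x = np.zeros(n_total)

    annotations: list[Annotation] = []
    comp_ranges: list[tuple[int, int]] = []
    murmur_ranges: list[tuple[int, int]] = []
    comps = sorted(config.components, key=lambda c: c.offset_in_cycle_s)

    for ci, start in enumerate(starts):
        next_start = starts[ci + 1] if ci + 1 < len(starts) else start + config.cycle_s
        placed = {}
        for comp in comps:
            onset = int(round((start + comp.offset_in_cycle_s) * fs))
            burst = make_component(comp.center_freq_hz, comp.duration_s,
                                   comp.amplitude, fs)
            offset = onset + len(burst)
            x[onset:offset] += burst
            annotations.append(Annotation(label=comp.label, onset_sample=onset,
                                          offset_sample=offset, fs=fs))
            comp_ranges.append((onset, offset))
            placed[comp.label] = (onset, offset)
        if config.murmur is not None:
            m = config.murmur
            if m.window == "systolic":
                lo_t = placed["S1"][1]
                hi_t = placed["S2"][0]
            else:
                # diastolic murmur decays before the next sound begins
                lo_t = placed["S2"][1]
                nxt = [c for c in comps if c.offset_in_cycle_s > S2.offset_in_cycle_s]
                if nxt:
                    hi_t = placed[nxt[0].label][0]
                else:
                    hi_t = int(round(next_start * fs)) - int(round(0.05 * fs))
            if hi_t - lo_t > 16:
                noise = _bandpassed_noise(hi_t - lo_t, m.band_lo_hz, m.band_hi_hz,
                                          fs, rng)
                fade = np.minimum(1.0, np.minimum(np.arange(hi_t - lo_t),
                                                  np.arange(hi_t - lo_t)[::-1]) / 20.0)
                x[lo_t:hi_t] += m.amplitude * noise * fade
                murmur_ranges.append((lo_t, hi_t))
        if config.click is not None:
            c = config.click
            onset = int(round((start + c.offset_in_cycle_s) * fs))
            burst = make_component(c.center_freq_hz, c.duration_s, 1.0, fs) \
                if c.duration_s * fs >= 8 else np.zeros(0)
            if len(burst) == 0:
                n_click = max(4, int(round(c.duration_s * fs)))
                tt = np.arange(n_click) / fs
                burst = np.sin(2 * np.pi * c.center_freq_hz * tt) * np.hanning(n_click)
            x[onset:onset + len(burst)] += c.amplitude * burst

    if config.noise_std > 0:
        x += config.noise_std * rng.standard_normal(n_total)

    signal = AudioSignal(samples=x, fs=fs)
    mask = RegionMask(component_ranges=tuple(comp_ranges),
                      murmur_ranges=tuple(murmur_ranges))
    truth = GroundTruth(annotations=annotations, region_mask=mask,
                        true_cycle_s=config.cycle_s)
    return signal, truth


def snr_to_noise_std(clean: AudioSignal, snr_db: float) -> float:
    """White-noise standard deviation giving the requested SNR vs the clean signal."""
    rms = float(np.sqrt(np.mean(clean.samples ** 2)))
    return rms / (10.0 ** (snr_db / 20.0))


def preset_catalog() -> dict[str, SynthConfig]:
    """Named generator configurations covering every evaluated category."""
    sys_murmur = MurmurSpec(window="systolic")
    dia_murmur = MurmurSpec(window="diastolic")
    return {
        "normal": SynthConfig(components=(S1, S2)),
        "systolic-murmur": SynthConfig(components=(S1, S2), murmur=sys_murmur),
        "diastolic-murmur": SynthConfig(components=(S1, S2), murmur=dia_murmur),
        "s3": SynthConfig(components=(S1, S2, S3)),
        "s4": SynthConfig(components=(S1, S2, S4)),
        "s3-murmur": SynthConfig(components=(S1, S2, S3), murmur=sys_murmur),
        "s4-systolic-murmur": SynthConfig(components=(S1, S2, S4), murmur=sys_murmur),
        "four-component": SynthConfig(components=(S1, S2, S3, S4)),
        "click": SynthConfig(components=(S1, S2), click=ClickSpec()),
    }
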