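"""Audio and annotation file I/O.

Recordings are exchanged as RIFF WAV (integer PCM or float); annotations —
labelled component boundaries — as JSON (canonical) or CSV (export).  All
sample values are floats scaled to [-1, 1] regardless of the on-disk
encoding, so downstream stages never see integer full-scale units.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.io import wavfile

logger = logging.getLogger(__name__)

#: labels a component annotation may carry
COMPONENT_LABELS = ("S1", "S2", "S3", "S4")
VALID_LABELS = COMPONENT_LABELS + ("unknown", "murmur")

_CSV_HEADER = ["label", "onset_sample", "offset_sample", "onset_s", "offset_s"]


class AudioIOError(ValueError):
    """Base error for audio/annotation file problems."""


class EmptyAudioError(AudioIOError):
    """The file decoded to zero samples."""


class UnsupportedAudioError(AudioIOError):
    """The WAV encoding is not a supported PCM/float format."""


class AnnotationFormatError(AudioIOError):
    """An annotation file violates the format or its invariants."""


@dataclass(frozen=True)
class AudioSignal:
    """A sampled single-channel waveform.

    Attributes
    ----------
    samples : np.ndarray
        Dimensionless amplitudes, finite floats.
    fs : float
        Sampling rate in Hz, > 0.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1:
            raise ValueError("AudioSignal holds a single channel (1-D array)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite (no NaN/Inf)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class Annotation:
    """A labelled, sample-accurate span of a recording.

    ``onset_s``/``offset_s`` are derived from the sample indices and the
    sampling rate of the annotated file; they are stored redundantly so the
    on-disk files are human-readable without knowing ``fs``.
    """

    label: str
    onset_sample: int
    offset_sample: int
    fs: float

    def __post_init__(self):
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if not self.onset_sample < self.offset_sample:
            raise ValueError(
                f"onset_sample ({self.onset_sample}) must precede "
                f"offset_sample ({self.offset_sample})"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def onset_s(self) -> float:
        return self.onset_sample / self.fs

    @property
    def offset_s(self) -> float:
        return self.offset_sample / self.fs

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def read_wav(path) -> AudioSignal:
    """Read a WAV file as a float signal in [-1, 1].

    Integer PCM is divided by its full scale (e.g. int16 by 32768); float
    data is passed through.  Multi-channel files return channel 0 with a
    logged warning — stethoscope recordings are single-channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        fs, data = wavfile.read(str(path))
    except ValueError as exc:
        raise UnsupportedAudioError(f"{path}: {exc}") from exc
    if data.size == 0:
        raise EmptyAudioError(f"{path}: zero-length audio")
    if data.ndim > 1:
        logger.warning(
            "%s has %d channels; using channel 0 only", path, data.shape[1]
        )
        data = data[:, 0]
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned
        samples = (data.astype(float) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.integer):
        full_scale = float(-np.iinfo(data.dtype).min)
        samples = data.astype(float) / full_scale
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(float)
    else:
        raise UnsupportedAudioError(f"{path}: dtype {data.dtype} not supported")
    return AudioSignal(samples=samples, fs=float(fs))


def write_wav(signal: AudioSignal, path) -> None:
    """Write a signal as float32 WAV."""
    wavfile.write(str(path), int(round(signal.fs)),
                  signal.samples.astype(np.float32))


def _validate_annotation_list(annotations: Sequence[Annotation]) -> None:
    """Component annotations must be sorted by onset and non-overlapping."""
    comps = [a for a in annotations if a.label in COMPONENT_LABELS]
    for prev, cur in zip(comps, comps[1:]):
        if cur.onset_sample < prev.onset_sample:
            raise AnnotationFormatError("component annotations not sorted by onset")
        if cur.onset_sample < prev.offset_sample:
            raise AnnotationFormatError(
                f"component annotations overlap: "
                f"[{prev.onset_sample},{prev.offset_sample}) and "
                f"[{cur.onset_sample},{cur.offset_sample})"
            )


def write_annotations(annotations: Sequence[Annotation], path) -> None:
    """Write annotations to the canonical JSON format (lossless)."""
    annotations = list(annotations)
    _validate_annotation_list(annotations)
    payload = {
        "format": "pcgseg-annotations",
        "version": 1,
        "annotations": [
            {
                "label": a.label,
                "onset_sample": int(a.onset_sample),
                "offset_sample": int(a.offset_sample),
                "onset_s": a.onset_s,
                "offset_s": a.offset_s,
                "fs": a.fs,
            }
            for a in annotations
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_annotations(path) -> list[Annotation]:
    """Read annotations from the canonical JSON format."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationFormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(payload, dict) or "annotations" not in payload:
        raise AnnotationFormatError(f"{path}: missing 'annotations' key")
    out = []
    for entry in payload["annotations"]:
        try:
            out.append(
                Annotation(
                    label=entry["label"],
                    onset_sample=int(entry["onset_sample"]),
                    offset_sample=int(entry["offset_sample"]),
                    fs=float(entry["fs"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise AnnotationFormatError(f"{path}: bad annotation entry: {exc}") from exc
    _validate_annotation_list(out)
    return out


def export_annotations_csv(annotations: Sequence[Annotation], path) -> None:
    """Export annotations as CSV (header: label,onset_sample,offset_sample,onset_s,offset_s)."""
    annotations = list(annotations)
    _validate_annotation_list(annotations)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for a in annotations:
            writer.writerow([a.label, a.onset_sample, a.offset_sample,
                             repr(a.onset_s), repr(a.offset_s)])
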