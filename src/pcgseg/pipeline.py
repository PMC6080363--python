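"""End-to-end orchestration: raw recording to labelled segmentation.

Stage order: standardize (2 kHz, denoise, unit peak) -> adaptive low-pass
murmur elimination -> morphological boundary detection -> cardiac-cycle
estimation -> S-transform component identification.  When the cycle cannot
be estimated (aperiodic or too-short input) the detected boundaries are
still returned with every label set to unknown — the failure mode of a
rhythm-dependent method, surfaced rather than guessed around.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioSignal, Annotation
from .boundary_detection import (BoundarySet, MorphologyParams,
                                 ThresholdParams, detect_boundaries)
from .cardiac_cycle import (CycleEstimate, CycleEstimationError,
                            FINAL_PEAK_FRAC, SIDE_PEAK_FRAC, estimate_cycle)
from .component_identification import (BEAT_WINDOW_FRAC, S3S4_PRIORS,
                                       LabeledComponent, Segmentation,
                                       build_segmentation,
                                       component_avg_frequencies,
                                       group_into_beats,
                                       instantaneous_frequency_from_signal,
                                       recognize_components)
from .murmur_elimination import CutoffParams, eliminate_murmurs
from .preprocessing import PreprocessParams, preprocess

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    """Every stage's configuration in one place (defaults = method constants)."""

    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    cutoff: CutoffParams = field(default_factory=CutoffParams)
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    thresholds: ThresholdParams = field(default_factory=ThresholdParams)
    side_peak_frac: float = SIDE_PEAK_FRAC
    final_peak_frac: float = FINAL_PEAK_FRAC
    max_ident_freq_hz: float = 300.0
    s3s4_rule: str = S3S4_PRIORS
    beat_window_frac: float = BEAT_WINDOW_FRAC


class StageError(RuntimeError):
    """An error tagged with the pipeline stage that raised it."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


def _run_stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except (CycleEstimationError,) as exc:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc


def segment_recording(signal: AudioSignal,
                      params: PipelineParams | None = None
                      ) -> tuple[Segmentation, dict]:
    """Run the full pipeline on one recording.

    Returns the segmentation and a diagnostics dict (cutoff, thresholds,
    cycle, per-beat component counts).
    """
    params = params or PipelineParams()
    if signal.n_samples == 0:
        raise ValueError("empty signal")

    pre = _run_stage("preprocess", preprocess, signal, params.preprocess,
                     clamp_level=True)
    filtered, cutoff = _run_stage("murmur_elimination", eliminate_murmurs,
                                  pre, params.cutoff)
    bs, env, bd_diag = _run_stage("boundary_detection", detect_boundaries,
                                  filtered, params.morphology, params.thresholds)
    diagnostics = {
        "cutoff_hz": cutoff.cutoff_hz,
        "found_valley": cutoff.found_valley,
        "n_components": bs.n_pairs,
        **bd_diag,
    }

    cycle: CycleEstimate | None = None
    try:
        if bs.n_pairs >= 2:
            cycle = estimate_cycle(env, fs=pre.fs,
                                   side_frac=params.side_peak_frac,
                                   final_frac=params.final_peak_frac)
        else:
            raise CycleEstimationError("fewer than two detected components")
    except CycleEstimationError as exc:
        logger.warning("cycle estimation failed (%s); labels set to unknown", exc)
        diagnostics["cycle_failure"] = str(exc)
        labeled = [
            LabeledComponent(label="unknown", beat_index=0, position_in_beat=k,
                             onset_sample=int(a), offset_sample=int(b),
                             avg_freq_hz=float("nan"))
            for k, (a, b) in enumerate(zip(bs.onsets, bs.offsets))
        ]
        return build_segmentation(labeled, fs=pre.fs, cycle=None), diagnostics

    diagnostics["cycle_s"] = cycle.avg_cycle_s
    inst = _run_stage("identification", instantaneous_frequency_from_signal,
                      pre, params.max_ident_freq_hz)
    avg_freqs = component_avg_frequencies(inst, bs)
    beats = group_into_beats(bs, cycle, params.beat_window_frac)
    diagnostics["beat_sizes"] = [len(b) for b in beats]
    labeled = recognize_components(beats, avg_freqs, bs, pre.fs,
                                   s3s4_rule=params.s3s4_rule)
    seg = build_segmentation(labeled, fs=pre.fs, cycle=cycle)
    logger.info("segmented %d components in %d beats (cycle %.3f s)",
                bs.n_pairs, len(beats), cycle.avg_cycle_s)
    return seg, diagnostics


def run_windowed(signal: AudioSignal, params: PipelineParams | None = None
                 ) -> Segmentation:
    """Segment in overlapping three-cycle windows and reconcile labels.

    The cycle is estimated once on the whole recording; windows of three
    cycles advance by two (one-cycle overlap).  A component seen by several
    windows keeps the majority label; ties become unknown.
    """
    params = params or PipelineParams()
    whole, diag = segment_recording(signal, params)
    if whole.cycle is None:
        return whole  # no periodicity: nothing to window over
    pre = preprocess(signal, params.preprocess, clamp_level=True)
    win = int(round(3 * whole.cycle.avg_cycle_samples))
    hop = int(round(2 * whole.cycle.avg_cycle_samples))
    n = pre.n_samples
    if win >= n:
        return whole

    starts = list(range(0, max(n - win, 0) + 1, hop))
    if starts[-1] + win < n:  # align the last window to the end, no sub-cycle tail
        starts.append(n - win)

    votes: dict[tuple[int, int], list[str]] = {}
    freqs: dict[tuple[int, int], float] = {}
    for start in starts:
        stop = start + win
        chunk = AudioSignal(samples=pre.samples[start:stop], fs=pre.fs)
        try:
            seg, _ = segment_recording(chunk, params)
        except (ValueError, StageError):
            seg = None
        if seg is not None:
            for comp in seg.components:
                # a component cut by an interior window edge is truncated;
                # the overlapping neighbour window sees it whole
                if comp.onset_sample <= 1 and start > 0:
                    continue
                if comp.offset_sample >= win - 2 and stop < n:
                    continue
                key = (comp.onset_sample + start, comp.offset_sample + start)
                votes.setdefault(key, []).append(comp.label)
                freqs[key] = comp.avg_freq_hz

    # cluster detections from different windows that refer to the same
    # component (onsets within 10 ms), then take the majority label
    merge_tol = int(round(0.01 * pre.fs))
    clusters: list[dict] = []
    for key, labs in sorted(votes.items()):
        if clusters and key[0] - clusters[-1]["onset"] <= merge_tol:
            clusters[-1]["labels"].extend(labs)
        else:
            clusters.append({"onset": key[0], "offset": key[1],
                             "labels": list(labs), "freq": freqs[key]})

    labeled = []
    for i, cl in enumerate(clusters):
        counts: dict[str, int] = {}
        # an unknown vote is an abstention: it carries no label information
        informative = [lab for lab in cl["labels"] if lab != "unknown"] or ["unknown"]
        for lab in informative:
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        winners = [lab for lab, c in counts.items() if c == best]
        label = winners[0] if len(winners) == 1 else "unknown"
        labeled.append(LabeledComponent(
            label=label, beat_index=-1, position_in_beat=i,
            onset_sample=cl["onset"], offset_sample=cl["offset"],
            avg_freq_hz=cl["freq"]))
    return build_segmentation(labeled, fs=pre.fs, cycle=whole.cycle)


def evaluate_against_truth(seg: Segmentation, truth_annotations: list[Annotation],
                           tol_s: float = 0.02) -> dict:
    """Boundary and label scores of a segmentation against ground truth."""
    from .metrics import confusion_metrics, match_detections

    pred = seg.to_annotations()
    pos = match_detections(pred, truth_annotations, tol_s=tol_s)
    lab = match_detections(pred, truth_annotations, tol_s=tol_s, require_label=True)
    se, ppv, acc = confusion_metrics(pos)
    lse, lppv, lacc = confusion_metrics(lab)
    return {
        "boundary": {"tp": pos.tp, "fn": pos.fn, "fp": pos.fp,
                     "se": se, "ppv": ppv, "acc": acc},
        "label": {"tp": lab.tp, "fn": lab.fn, "fp": lab.fp,
                  "se": lse, "ppv": lppv, "acc": lacc},
    }
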