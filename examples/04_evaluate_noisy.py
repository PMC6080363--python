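"""Score the pipeline on a degraded recording against exact ground truth.

Adds 15 dB SNR white noise and ±5% per-cycle timing jitter to a
four-component recording, segments it, and reports event-detection scores
(sensitivity, positive predictive value) at 20 ms onset tolerance.
"""

from dataclasses import replace

from pcgseg.pipeline import evaluate_against_truth, segment_recording
from pcgseg.synthetic import generate, preset_catalog, snr_to_noise_std

cfg = preset_catalog()["four-component"]
clean, _ = generate(replace(cfg, seed=8))
noise_std = snr_to_noise_std(clean, 15.0)
signal, truth = generate(replace(cfg, seed=8, noise_std=noise_std,
                                 timing_jitter_frac=0.05))

segmentation, _ = segment_recording(signal)
scores = evaluate_against_truth(segmentation, truth.annotations, tol_s=0.02)

print("labels:", [c.label for c in segmentation.components])
b, l = scores["boundary"], scores["label"]
print(f"boundary: Se {b['se']:.1f}%  PPV {b['ppv']:.1f}%  "
      f"(TP {b['tp']}, FN {b['fn']}, FP {b['fp']})")
print(f"labelled: Se {l['se']:.1f}%  PPV {l['ppv']:.1f}%")
print("\nA true positive is a detection whose onset lies within 20 ms of a "
      "ground-truth onset (and, for the labelled score, carries the right "
      "label).")
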