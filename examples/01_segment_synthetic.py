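"""Segment a clean synthetic phonocardiogram and print the labelled result.

Builds a three-cycle S1/S2/S3 recording with exact ground truth, runs the
full pipeline (denoise -> adaptive low-pass -> morphological boundary
detection -> cycle estimation -> S-transform labelling) and prints every
component with its boundaries and average instantaneous frequency.
"""

from pcgseg.pipeline import segment_recording
from pcgseg.synthetic import generate, preset_catalog

signal, truth = generate(preset_catalog()["s3"])
segmentation, diagnostics = segment_recording(signal)

print(f"ALPF cutoff: {diagnostics['cutoff_hz']:.1f} Hz "
      f"(valley found: {diagnostics['found_valley']})")
print(f"estimated cycle: {segmentation.cycle.avg_cycle_s:.3f} s "
      f"(true {truth.true_cycle_s:.3f} s)")
print(f"{'label':>8} {'onset_s':>8} {'offset_s':>9} {'avg_freq_Hz':>12}")
for c in segmentation.components:
    print(f"{c.label:>8} {c.onset_sample / 2000:8.3f} "
          f"{c.offset_sample / 2000:9.3f} {c.avg_freq_hz:12.1f}")
print("\nintervals:")
for iv in segmentation.intervals:
    print(f"  {iv['name']:>5}: {iv['duration_s']:.3f} s")
print("\nS3 carries the lowest average instantaneous frequency — that is "
      "what separates the gallop sound from S1/S2.")
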