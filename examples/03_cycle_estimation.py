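"""Cardiac-cycle estimation from the boundary envelope.

Shows why the unbiased autocorrelation (divisor N - m) is used instead of
the biased one (divisor N): on a periodic envelope the unbiased primary
peaks stay at full height, so simple thresholding isolates the cycle lag.
"""

import numpy as np

from pcgseg.boundary_detection import detect_boundaries
from pcgseg.cardiac_cycle import estimate_cycle, pacf, uacf
from pcgseg.murmur_elimination import eliminate_murmurs
from pcgseg.preprocessing import preprocess
from pcgseg.synthetic import generate, preset_catalog

signal, truth = generate(preset_catalog()["normal"])
pre = preprocess(signal, clamp_level=True)
filtered, _ = eliminate_murmurs(pre)
boundaries, envelope, _ = detect_boundaries(filtered)

period = int(truth.true_cycle_s * 2000)
u = uacf(envelope.values).values
p = pacf(envelope.values).values
for k in (1, 2):
    lo, hi = k * period - 100, k * period + 100
    print(f"peak near lag {k}P: unbiased {u[lo:hi].max():.4f}   "
          f"biased {p[lo:hi].max():.4f}")

est = estimate_cycle(envelope)
print(f"\nestimated cycle: {est.avg_cycle_samples:.0f} samples "
      f"= {est.avg_cycle_s:.3f} s (true {truth.true_cycle_s} s), "
      f"from peak lags {est.peak_lags.tolist()}")
print("The biased peaks shrink with lag; the unbiased ones do not, which "
      "is what lets a fixed 0.4/0.5 fraction-of-max threshold find them.")
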