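"""Adaptive low-pass murmur elimination versus a fixed 200 Hz cutoff.

Generates a recording with a systolic murmur (band-limited noise between
S1 and S2), finds the adaptive cutoff from the FFT envelope, and compares
the signal-murmur ratio (SMR, dB of component energy over murmur-region
energy) before and after each filter.
"""

from pcgseg.metrics import smr
from pcgseg.murmur_elimination import CutoffResult, apply_alpf, eliminate_murmurs
from pcgseg.preprocessing import preprocess
from pcgseg.synthetic import generate, preset_catalog

signal, truth = generate(preset_catalog()["s4-systolic-murmur"])
pre = preprocess(signal, clamp_level=True)
filtered, cutoff = eliminate_murmurs(pre)
fixed = apply_alpf(pre, CutoffResult(200.0, cutoff.primary_peak_hz, False))

smr_ori = smr(pre, truth.region_mask)
smr_alpf = smr(filtered, truth.region_mask)
smr_200 = smr(fixed, truth.region_mask)

print(f"primary spectral peak : {cutoff.primary_peak_hz:6.1f} Hz")
print(f"adaptive cutoff       : {cutoff.cutoff_hz:6.1f} Hz")
print(f"SMR original          : {smr_ori:6.2f} dB")
print(f"SMR adaptive low-pass : {smr_alpf:6.2f} dB  (gain {smr_alpf - smr_ori:+.2f} dB)")
print(f"SMR fixed 200 Hz      : {smr_200:6.2f} dB  (gain {smr_200 - smr_ori:+.2f} dB)")
print("\nThe adaptive cutoff sits just above the heart-sound band, so it "
      "removes the murmur energy between 150 Hz and the fixed cutoff that "
      "a 200 Hz low-pass leaves behind.")
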