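# Methods

This note documents the models and numerical choices behind `pcgseg`: what
each stage assumes, which parameters matter, what the synthetic generator
does and does not emulate, and where the design was genuinely open.

## Signal model and assumptions

A phonocardiogram is modelled as a quasi-periodic train of transient
components over a quiet baseline: S1 and S2 (roughly 80–150 Hz, ~100 ms)
bounding systole in every beat, optionally S3 (early diastole, just after
S2) and/or S4 (late diastole, just before the next S1) at 20–70 Hz and
~50 ms, plus murmurs — sustained band-limited noise above ~150 Hz occupying
systolic or diastolic intervals — and occasional short clicks. Two
assumptions carry the whole method: component energy is concentrated below
~200 Hz with gallop sounds clearly below S1/S2 in frequency, and the rhythm
is regular enough that one average cycle length describes the recording.
The second assumption is the method's hard limitation: under strong rhythm
irregularity the cycle estimate fails and components cannot be labelled
(they are still detected and reported as `unknown`).

## Stages and parameters

**Standardization.** Resampling to `target_fs = 2000` Hz uses polyphase FIR
resampling (anti-aliasing included); 2 kHz is twice the assumed 1 kHz
maximum heart-sound frequency. Denoising is soft thresholding of the db4
DWT detail coefficients at level 7 with symmetric extension. The threshold
magnitude is the universal threshold `σ̂·sqrt(2 ln N)` with `σ̂` estimated
from the median absolute deviation of the finest-detail coefficients;
approximation coefficients are never thresholded. The shrinkage is computed
directly (`sign(c)·max(|c|−thr, 0)`) rather than through the library
helper, which returns NaN for exactly-zero coefficients. Unit-peak
normalization makes every later amplitude threshold relative to the loudest
component; all-zero input is an error.

**Adaptive low-pass murmur elimination.** The one-sided FFT magnitude is
smoothed by a three-branch moving average whose windows shrink at the
sequence edges (the divisor is the number of valid bins — windows are
clipped, not zero-padded). The neighbourhood radius `L_F = 5` bins is small
enough not to merge adjacent spectral peaks. On the unit-peak envelope, the
primary peak is the global maximum (restricted to ≤200 Hz if the global
maximum implausibly falls above it); the cutoff is the first strict local
minimum after it, inside 20–200 Hz, with value below the 0.2 coefficient
threshold; plateaus collapse to their first bin; without such a valley the
cutoff is 200 Hz. The filter itself is an order-6 Butterworth applied
forward–backward: the filter realization is not dictated by the method, and
zero phase is required so that component onsets stay aligned for boundary
detection. Caveat observed on synthetic data: with pure-tone components the
spectral envelope dips below 0.2 immediately past the S2 lobe, so the
cutoff can sit at the band edge and shave ~20% of S2's amplitude without
affecting boundaries or labels; real components are broadband and are
affected less.

**Boundary detection.** The envelope is the flat-element morphological
closing (windowed maximum then minimum) of the *rectified* signal: the
upper envelope of the signed signal would miss negative lobes. Windows are
centred with left radius `⌊Q/2⌋` and shrink at the edges; the second stage
of each closing/opening uses the reflected element, which is what makes
closing extensive and opening anti-extensive for even element lengths. The
closing length `Q = 30` samples (15 ms) must stay below the shortest
inter-component gap (≥100 ms) or components would merge; the opening length
`Q' = 50` (25 ms) must stay below the shortest component (~50 ms) or real
components would vanish. The adaptive threshold `θ = min(λ·std, θ_C)` with
`λ = 0.8`, `θ_C = 0.025` (population std, divisor N) separates murmur
residue from component skirts while staying small enough to preserve
boundary detail. Candidate onsets/offsets are the zero samples immediately
before/after each non-zero run (runs touching the sequence edge take the
edge index; runs separated by a single zero sample are merged, since that
sample would have to serve as both an offset and the next onset). The
per-run energy threshold `η = 0.25` on the re-normalized opened envelope
removes what survives opening; ties are kept. Endpoint samples of a run are
zeros and contribute nothing to the energy either way.

**Cycle estimation.** The unbiased autocorrelation is computed by FFT
(`scipy.signal.correlate`) and divided by `N−m`; at the largest lag a
single product remains. Side peaks (S1×S2 alignments) are suppressed by
squaring and thresholding at `0.4·max`; the last surviving peak is removed
outright because the shrinking divisor inflates far lags (if only one peak
region exists it is kept, with a warning, since removing it would destroy
the sequence). A second unbiased autocorrelation is thresholded at
`0.5·max`; a "peak" of a thresholded sequence is a maximal non-zero run
represented by its argmax lag, the origin run is excluded, and the cycle is
the mean gap between consecutive peak lags (a single surviving peak
contributes its own lag — with one peak there are no gaps to average).
Fewer than one non-origin peak raises a cycle-estimation error; the
pipeline then emits boundaries with `unknown` labels rather than guessing.

**Identification.** The discrete Stockwell transform is evaluated row-wise:
row `n` is the inverse DFT of the spectrum circularly shifted by `n` bins
and weighted by the Gaussian voice window `exp(−2π²m²/n²)` over
`m = 0..N−1`; the zero-frequency row is the signal mean (the printed
zero-branch of the defining sum omits the signal and is dimensionally
inconsistent; the mean is the standard choice). Rows are computed only up
to 300 Hz — transform values are identical to the corresponding rows of the
full transform, and the adaptive low-pass has already removed energy above
that — and the per-column weighted mean frequency is accumulated row by row
so memory stays O(N) on long recordings. The frequency axis follows the
halved convention `F(m) = m·f_s/(2N)`; this scales all frequencies by one
half uniformly, and only their ordering enters the classifier. Beats are
windows of `0.92` cycles anchored at each first unassigned component onset.
A fixed grid from the first onset was considered and rejected: sub-percent
cycle-estimate error accumulates linearly across the grid and flips
components whose onsets coincide with grid boundaries, whereas per-beat
anchoring cannot drift. The margin 0.92 lies between the latest
within-beat onset the generator produces (S4 at 0.85 of the cycle) and the
earliest next-beat onset under ±5% jitter (0.95). Two-component beats
compare the intra-beat gap against the gap to the next beat's first
component (tail beats reuse the majority orientation of earlier beats).
In three-component beats the lowest-frequency component is the gallop; its
cyclic neighbours are S2 (before) and S1 (after), and S3 vs S4 is resolved
by the timing priors — close to the preceding S2 means S3, close to the
following S1 means S4 (`s3s4_rule="verbatim"` flips this comparison for
the alternative reading). Gallops at a recording edge lack one of the two
gaps and take the majority decision of fully-informed beats.
Four-component beats take the two lowest-frequency components as S3 then S4
in cyclic order; if those two are not cyclically adjacent the frequency
evidence is inconsistent (S3 and S4 are always neighbours) and the beat is
flagged `unknown`, as is any beat with fewer than 2 or more than 4
components.

**Windowed processing.** Long recordings may be processed in windows of
three estimated cycles advancing by two (one-cycle overlap). Components cut
by an interior window edge are ignored (the neighbouring window sees them
whole); labels of components seen by several windows are reconciled by
majority, with `unknown` votes treated as abstentions and ties resolved to
`unknown`.

## Evaluation machinery

Detections are matched to ground truth greedily in time order, one-to-one,
within an onset tolerance (default 50 ms; the end-to-end tests use 20 ms,
half the minimum inter-component gap). Unmatched detections are FP,
unmatched truths FN; the label-aware variant counts a position match with
the wrong label as both FP and FN. Event detection has no negative class,
so TN = 0 and accuracy reduces to TP/(TP+FN+FP). SMR masks come from the
generator's exact component/murmur spans and are held fixed across filters.
The paired t statistic uses the sample standard deviation (divisor n−1);
critical values come from the Student-t quantile function, not a table.

## Synthetic generator

Each component is a Gaussian-windowed sinusoid. The window standard
deviation is duration/4, so the span edges sit at 2σ (≈ −17 dB) and the
sound keeps substantial amplitude across most of its nominal duration, the
way auscultated components do — this matters because the morphology
parameters assume a ~50 ms gallop sound is ~100 samples of real signal, not
a narrow blip. Outside the span the envelope is exactly zero, so the −40 dB
envelope crossing coincides with the span edge, which is the ground-truth
boundary. Default layout per 0.8 s cycle: S1 (100 Hz, 0.10 s, amplitude
1.0) at 0.00 s, S2 (120 Hz, 0.10 s, 0.8) at 0.30 s, S3 (45 Hz, 0.05 s,
0.40) at 0.55 s, S4 (35 Hz, 0.05 s, 0.35) ending 0.07 s before the next
S1 — satisfying the timing priors (S1S2 0.20 < S2S1; S2S3 0.15 < S3S1 0.20;
S2S4 0.28 > S4S1 0.07). Murmurs are band-passed white noise (150–450 Hz,
peak amplitude 0.15 of S1) confined to the systolic or diastolic window
with a short fade; 0.15 was chosen so the original signal-murmur ratio
comes out near 18 dB, the level reported for real murmur recordings.
Diastolic murmurs end 50 ms before the next S1. Clicks are 10 ms, 300 Hz
bursts at amplitude 0.12. White noise and per-cycle timing jitter
(uniform, ±fraction of the cycle) are driven by one seeded generator, so
recordings are bit-reproducible.

What the generator does *not* emulate: broadband component spectra (tones
overstate band-edge attenuation by the adaptive filter), split S1/S2
morphology, respiratory amplitude modulation, baseline wander, sensor
artifacts, and genuinely pathological murmur shapes (crescendo/decrescendo).
Perfect scores on clean presets therefore demonstrate the pipeline's
correctness under its own assumptions, not clinical performance.

## Problem sizes and robustness conditions

Tests and the acceptance script run 3-cycle recordings (2.4 s at 2 kHz) per
preset — the segment length the method is designed around — and evaluate
the degraded condition (15 dB SNR white noise, ±5% per-cycle jitter) pooled
over presets and 20 seeds. Pooling matters: a single unlucky jitter
realization can split the autocorrelation's true-period peaks into
single-beat-pair humps that fall below the 0.4 suppression threshold while
a far, divisor-inflated lag survives, mis-estimating the cycle and voiding
every label in that recording — the same failure mode the method exhibits
on genuinely arrhythmic recordings. Boundary detection is unaffected (it
precedes cycle estimation), which is why boundary sensitivity stays near
98% while pooled label accuracy sits a few points lower.

## Known limitations

* No handling of severe arrhythmia; one average cycle per recording.
* Beat-by-beat (instantaneous) cycle tracking is out of scope.
* The moving-average and morphology edge conventions (clipped windows) and
  the one-sample onset convention (the zero sample *before* the first
  non-zero sample) are documented choices; other conventions shift
  boundaries by at most a couple of samples.
* `match_detections` is greedy, not optimal assignment; at the tolerances
  used the difference is immaterial.
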