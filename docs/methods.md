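# Methods

This note documents the models, numerical choices and limitations behind
`opmbci`. It describes what the code computes; every number quoted here
is produced by the test suite or `scripts/acceptance.py` at run time.

## Synthetic sessions

The generator emulates the two stimulation paradigms the pipeline is
built for. It is first-class, tested code — not a fixture — because the
kind of multichannel OPM/EEG recordings the pipeline targets are
typically unavailable publicly.

**Motion-onset ERP sessions.** 45 trials; in each trial one of nine
crosses is cued and all nine are stimulated 5 times in pseudorandom
block order (every block of nine stimulations is a permutation), with a
150 ms stimulation and a uniformly jittered inter-stimulus interval of
150 ± 75 ms. Each stimulation of the *cued* cross adds two evoked
components; other stimulations add nothing. A component is a
Gaussian-windowed half-sine parameterised by latency, width and
amplitude; it reaches exactly its nominal amplitude at the latency
sample. Defaults: an N/M200-like deflection at 191 ms (−567.34 fT,
100 ms wide) and a P/M300-like deflection at 347 ms (1103.38 fT,
160 ms wide) — canonical motion-onset values for magnetometers.
Magnetometers see a signed dipolar spatial gain
g(x) = (x/σ)·exp(−r²/2σ²), so neighbouring sensors across the source
show a polarity reversal (the effect synthetic planar gradiometers
exploit); EEG sees a single-signed Gaussian gain. Gains are normalised
to unit maximum magnitude so component amplitudes are in sensor units at
the best channel.

**SSVEP sessions.** Either a single square flickering at the integer
frequencies 8–12 and 25–29 Hz (10 repetitions each, 4-s trials, 100
trials total) or a nine-target grid where each target carries a unique
(frequency, phase) pair and each target is cued `reps` times in block
order (8 reps → 72 trials). The response on a channel with gain g is
g·A·cos(2πf·t + φ − 2πf·L): the visual-system latency L (default 0.1 s)
shifts the response phase by −2πfL, producing the expected negative
phase-versus-frequency trend. The cosine-at-onset convention matches the
phase extracted by `ssvep.phase_at`.

**Noise.** White Gaussian noise (σ_w) plus 1/f^β noise (β = 1 by
default) synthesised by shaping a complex white spectrum with f^(−β/2);
each channel of the 1/f component is rescaled to an empirical standard
deviation equal to its scale parameter. The 1/f term reflects the higher
low-frequency noise floor of OPMs. Defaults σ_w = 200 and
pink scale = 200 (fT), i.e. a total sensor-noise σ of ≈ 283 fT.

**Default target layout.** Three frequencies crossed with three phases
{0, 2π/3, 4π/3}. The frequencies are {7.5, 10, 12.5} Hz, chosen so that
at the 150 Hz decoding rate two flicker periods are exactly 40, 30 and
24 samples and the 50%-overlap steps (20, 15, 12) are whole numbers of
periods. With incommensurate frequencies (e.g. 9 Hz at 150 Hz) the
rounded segment step drifts relative to the flicker phase by up to
0.04 period per step; across a 4-s epoch this smears the averaged
two-period template several-fold and measurably degrades exactly the
drifting-frequency targets. Real frequency-phase spellers choose
frequencies matched to the presentation/acquisition grid for the same
reason. The layout, like the sampling rates, is fully configurable.

**What the generator does not emulate:** eye movements, head-movement
artifacts, sensor calibration drift, inter-trial latency jitter of the
neural response, harmonics of the flicker response, or any forward head
model. Passing tests therefore demonstrate correctness of the analysis
chain under the stated signal model, not performance on real recordings.

## Preprocessing

Conventions: 0-based sample indices, half-open windows [start, end).

* Band-pass filtering is a 4th-order Butterworth applied forward and
  backward (zero phase; the magnitude response is the square of the
  one-pass prototype). Odd-reflective padding of at least 3× the filter
  order handles the edges. ERP analysis uses 0.5–15 Hz, SSVEP 4–40 Hz.
* Epoching cuts [onset + tmin, onset + tmax); events whose window
  exceeds the recording are skipped and counted in the log.
* Baselining subtracts each epoch's per-channel mean over the 200 ms
  pre-onset window.
* Downsampling (default to 150 Hz) uses polyphase anti-aliased
  resampling with linear-trend edge padding; output length is
  floor(n·fs_new/fs).
* Synthetic planar gradiometers are first-minus-second magnetometer
  differences ("all-pairs", "neighbours" within a distance, or explicit
  pairs); the sign convention is irrelevant downstream. Over opposite
  poles of a dipolar field the signal doubles while independent sensor
  noise grows by √2, an amplitude-SNR gain of √2.
* Two-period segmentation uses n = round(2·fs/f) samples and
  step = round(n·(1 − overlap)); a trailing partial segment is dropped.
  Segments starting before `discard_before_ms` are removed (the
  spelling mode discards the initial 150 ms onset transient).

## Evoked statistics

The target ERP/F averages the epochs whose stimulated cross equals the
cued one. Confidence intervals are bias-corrected and accelerated (BCa)
bootstrap intervals with 1000 resamples at the 95% level, delegated to
`scipy.stats.bootstrap`; peak-latency intervals bootstrap over epoch
indices so whole epochs are resampled jointly. For heavily discrete
statistics (latency on the sample grid) the BCa bias/acceleration terms
can be undefined; the implementation then degrades to the percentile
interval of the same bootstrap distribution, and to a zero-width
interval for constant distributions. Component SNR is
10·log₁₀(P_window/P_baseline), the power ratio of the evoked mean in a
100 ms window centred on the peak latency versus the 200 ms pre-onset
baseline, with a percentile bootstrap CI — the power-ratio reading of
"SNR against baseline" is a package decision and is recorded in the
output metadata; peak search windows default to 150–250 ms (N/M200) and
280–450 ms (P/M300).

## SSVEP features

The amplitude spectrum uses the |DFT|/N normalisation (the choice
cancels in the SNR ratio). Spectral SNR divides the bin amplitude at the
gazed frequency by the mean of the six neighbouring bins on each side
(12 bins, excluding the target bin, DC and Nyquist); requesting an
off-bin frequency is an error rather than a silent interpolation, and a
vanishing neighbour mean (noise-free sinusoid) yields a capped ratio of
10⁶ with a warning. Phase is the argument of the DFT coefficient in the
cosine-at-onset convention, in (−π, π]. Circular standard deviation is
√(−2 ln R̄) (via `scipy.stats.circstd`), with an infinite sentinel when
the resultant length vanishes. Per-epoch SNR is computed first and
averaged afterwards when summarising sessions.

## Decoder

Vectorisation is channel-major (channel 1's n samples, then channel
2's, …) identically for patterns, covariance segments and scored data.
The covariance is the mean-centred 1/(N−1) estimate over vectorised
segments, regularised as Σ̂ = αΣ + (1 − α)I with α = 0.95; the
pseudo-inverse discards singular values below 10⁻¹⁰ of the largest.
The SSVEP model trains one beamformer per target: the pattern is the
average two-period segment of that target's cued epochs, while the
covariance pools segments of *all* epochs cut at that target's segment
length. The ERP model is a single beamformer whose pattern is the
vectorised average target epoch and whose covariance uses all epochs.
Classification takes the maximal beamformer output; ties break to the
lowest target index for determinism. Cross-validation is stratified with
seeded shuffling; ERP folds are assigned to whole trials so no epoch of
a test trial enters training. Greedy forward channel selection adds the
candidate maximising the CV score (SSVEP: fourfold CV accuracy; ERP:
mean fivefold CV accuracy over 1–5 stimulus repetitions) and stops at
100% or when no candidate strictly improves.

## Speller

Eight characters (the word's unique letters plus random fillers) and a
backspace are placed on random targets per word. The simulated user
gazes the next needed character, or the backspace after a decoding
error, until the working text equals the target word; the session is
capped against pathological decoders and flagged as aborted if the cap
is hit. Stopping on text equality (rather than on text length) is
deliberate: with the backspace policy, a final-position error would
otherwise end a word in a misspelled state. Each 2-s stimulation epoch
is synthesised, band-pass filtered 4–40 Hz, matched to the decoder rate
and classified with the onset-discard rule. The post hoc length sweep
truncates the session's epochs to their initial 0.25–2.0 s (0.25 s
steps) and re-classifies them; when a truncation is too short for the
150 ms discard to leave any segment, scoring falls back to the
undiscarded segmentation, and targets whose two-period window exceeds
the truncated epoch score −∞. The 20-s habituation period of a real
session is schedule metadata with no signal consequence.

## Problem sizes

Tests and the acceptance script run on scaled-down but structurally
complete sessions: a 6-sensor occipital patch, 600 Hz acquisition
downsampled to 150 Hz for SSVEP (250 Hz → 50 Hz for the ERP decoder),
72-trial training sessions, 900 trials for the chance-level check, and
10⁴-draw / 500-replicate statistic oracles. These sizes were chosen so a
full run completes in about a minute on one CPU while keeping every
count that matters (9 targets, 8 cue repetitions, 45 ERP trials with
5 stimulations per cross) at its nominal value.

## Known limitations

* The LCMV covariance grows as (m·n)²; large channel counts at high
  sampling rates require downsampling or channel selection first.
* BCa intervals on strongly discrete statistics fall back to percentile
  intervals (see above).
* The generator's phase model is exact (no inter-trial phase jitter), so
  phase-coded decoding on synthetic data is easier than on real OPM
  recordings, where inter-trial phase variability is the documented
  weak point of the modality.
* Source-space decoding, harmonic-combination SSVEP features and
  alternative classifiers (CCA/TRCA) are out of scope.
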