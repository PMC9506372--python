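# Methods

## The estimation problem

Personalizing theta-band neurostimulation (tACS/otDCS) requires each
participant's *individual theta frequency* (ITF): the 4–8 Hz rhythm that
dominates their EEG while they successfully encode new associations.
Group-average theta peaks hide large individual differences in both peak
frequency and latency, and simple spectral peak-picking cannot guarantee that
a detected peak truly dominates its neighbours.  The approach implemented
here treats the frequency with the highest event-related power in each of
many small time-window × electrode cells as a repeated measurement of the
same underlying encoding rhythm, takes the mode over cells as the ITF, and
reports the fraction of cells carrying that mode as a per-person reliability
index.

## Pipeline

1. **Conditioning.** The continuous recording is high-pass filtered at
   0.1 Hz (order-4 Butterworth, zero-phase) and power-line interference at
   50 Hz is removed with a zero-phase IIR notch (Q = 50; a multitaper
   regression variant in the style of CleanLine is available via
   `line_method="spectrum_fit"`).  Manual artifact screening is replaced by
   an automated any-channel peak-to-peak criterion (default 150 µV) plus an
   explicit excluded-channel list; the threshold is configurable because no
   numeric criterion is canonical.

2. **Epoching and labeling.** Epochs span −1000…2500 ms around encoding
   onsets, DC-corrected to the −800…0 ms pre-stimulus mean.  An encoding
   trial is labeled *successful* when its intact pair was later judged "old"
   in the recognition block, *unsuccessful* when judged "recombined", and
   *unlabeled* otherwise (omitted responses are excluded rather than counted
   as failures).  Only successful epochs enter the ITF analysis.

3. **Time–frequency decomposition.** Complex Morlet wavelets with a fixed
   7 cycles, 1–15 Hz in 0.5 Hz steps.  Each wavelet is normalized so its
   spectral peak gain is one: a sinusoid of amplitude A yields power A² at
   its own frequency wherever it sits on the grid, making peak powers
   comparable across frequencies.  (Unit-energy normalization would instead
   scale tone power as 1/f, breaking that comparability.)

4. **ERSP.** Power is expressed as a ratio against the mean power in the
   −800…0 ms baseline, per channel and frequency, reported on 2–15 Hz.
   The ratio is applied to the trial-averaged power (see "Averaging order"
   below).  A ratio of 1 means no event-related change.

5. **Peak matrix and ITF.** ERSP is averaged within 19 overlapping 100 ms
   windows stepped by 50 ms across 250–1250 ms post-onset, at six
   centroparietal electrodes (Cz, C3, C4, Pz, P3, P4) — 114 cells.  Each
   cell records the grid frequency with the highest windowed ERSP (argmax
   ties resolve to the lower frequency).  The ITF is the modal frequency
   among cells peaking inside theta, defined as the half-open [4, 8) Hz so
   the candidates are {4.0, …, 7.5}; 8.0 Hz counts as alpha.  Reliability =
   (cells equal to the ITF)/(theta cells), classified as singular (>0.80),
   highly reliable (0.50–0.80], reliable (0.30–0.50], unreliable
   [0.15–0.30], or none (<0.15, the chance level for eight candidates).
   Multimodal count distributions set a tie flag and resolve toward the
   candidate with the larger summed ERSP over its cells.

6. **Fallback.** When fewer than 20% of cells (configurable) peak in theta,
   the matrix is rebuilt with PO7/PO8 appended (19 × 8 cells) and the ITF
   re-extracted, flagged `fallback_used`.

7. **Control.** Resting-state EEG is segmented into consecutive 3500 ms
   pseudo-epochs whose first 1000 ms serve as baseline, then pushed through
   the identical analysis.  Across subjects, task-vs-rest theta shares are
   compared with a two-sided Wilcoxon signed-rank test (the source analysis
   reports only a significance level; the signed-rank test is the standard
   paired nonparametric choice at this sample size).

## Numerical choices that matter

**Averaging order.**  Two ERSP variants exist: divide each trial by its own
baseline then average (`per_trial=True`), or divide the trial-averaged power
by the trial-averaged baseline (default).  They coincide for homogeneous
trials, but on stochastic data the single-trial variant is strongly biased
upward at low frequencies: the 800 ms baseline holds only ~2–3 independent
samples of a 7-cycle theta wavelet, so E[P/B̂] ≫ E[P]/E[B] (measured mean
ratios of 1.4–1.9 at 2–5 Hz for stationary noise).  That bias tilts
per-cell argmax toward low frequencies and destroys calibration (stationary
input should give ratio ≈ 1), so the ratio-of-averages form is the default
and the one used by the pipeline.

**Edge handling.**  For bare epochs the decomposition pads by symmetric
reflection (at least half the longest wavelet).  Reflection, however, is
*coherent* with strongly autocorrelated EEG background — the reflected slow
component continues the interior signal — which measurably biases near-edge
power of 1/f-like signals, and the −800…0 ms baseline sits near the epoch's
left edge.  The pipeline therefore cuts epochs with 1800 ms of real signal
context on each side (`epoch_buffer_ms`), uses plain linear convolution, and
crops afterwards: every analysis-band wavelet (longest 1.75 s at 2 Hz) then
sees genuine data throughout the reported time range.  Time points within
half a wavelet of an edge are flagged per frequency in `TFRArray.valid`.

**Decomposition vs analysis grid.**  Decomposition runs from 1 Hz as
specified for the transform, but ERSP reporting starts at 2 Hz: at 1 Hz a
7-cycle wavelet lasts 7 s, twice the epoch, so those rows are uninformative.

**Precision.**  The FFT convolution runs in single precision by default
(~7 significant digits; power ratios need far less) which halves memory
traffic; `precision="double"` is available.

**Degenerate inputs.**  Zero baseline power raises an error naming the
offending (trial, channel, frequency); all-trials-rejected raises with
advice to review the threshold; reliabilities outside [0, 1] are rejected.

## The synthetic-data generator

`simulate_session` produces a full encoding/recognition session with known
ground truth: 42 face–scene pairs presented for 2000 ms with 1250–1750 ms
inter-stimulus intervals, 84 recognition probes (42 intact, 42 recombined),
and a behavior table with a configurable hit rate (default 0.6, ≈25
successfully encoded trials, overall accuracy ≈64% with the default
correct-rejection rate of 0.68).  The EEG is a sum of:

* 1/f Gaussian background (default exponent 1.0, 10 µV RMS), independent
  across 20 channels of the 10–10 montage;
* a continuous 10 Hz alpha rhythm, strongest over PO7/PO8/Oz;
* Hann-windowed theta bursts at the planted frequency on the six
  centroparietal channels, time-locked to the onsets of the trials that
  will later be judged "old".  Burst phase is random per trial — the
  conservative case for power-based detection.  Unsuccessful trials receive
  no burst, encoding the assumption that theta marks successful encoding.

Burst amplitude is calibrated empirically per session: the generator
measures the background wavelet power at the planted frequency and the peak
wavelet power of a unit burst, then scales so that burst power/background
power equals `burst_snr` (default 3).

**Burst duration.**  The default burst lasts 1000 ms, filling the scanned
250–1250 ms interval, with latency jitter truncated so bursts stay inside
it.  Shorter bursts are spectrally too broad to carry a frequency defined at
the 0.5 Hz grid: a 700 ms Hann burst at 5.5 Hz holds ~2 effective cycles
(spectral FWHM ≈ 2 Hz), and dividing by a 1/f baseline then shifts the
ERSP argmax to the upper neighbour even in the noise-free limit — the
planted frequency would be unrecoverable by construction, not by noise.

**What the generator does not emulate:** volume conduction and spatially
correlated background, eye/muscle artifacts, non-stationary alpha power,
burst-frequency drift within a session, and recognition-phase EEG (the
event table lists recognition onsets beyond the recorded span; the method
never analyzes them).  Passing recovery tests therefore demonstrates that
the pipeline is correct and well-calibrated for signals with this
statistical structure — not that real recordings will yield reliabilities of
any particular magnitude.

## Recovery performance and its physical limit

Grid-exact recovery of a planted frequency requires distinguishing f0 from
f0 ± 0.5 Hz.  With 7-cycle wavelets (power response ≈ 0.88 at +0.5 Hz near
5.5 Hz), a ≤1 s Hann burst, and the upward tilt from baseline-ratio
normalization against a 1/f background, the noise-free margin in favour of
f0 is only 1–4%.  The binding noise source is the baseline *estimate* in the
ERSP denominator: with ~25 successful trials and ~2–3 independent baseline
samples per trial per theta wavelet, per-electrode denominator noise is
~10%, and a denominator fluctuation flips an electrode's whole row of cells
together.  Recovery rates of roughly 85–100% per planted frequency at the
default conditions (burst SNR 3, ~25 successful epochs) are the expected
regime — lowest in mid-theta, where neither the band edge nor the alpha
rhythm suppresses a neighbour — with misses essentially always to the upper
adjacent 0.5 Hz neighbour,
mirroring the fact that in real data the modal value carries only about
half of the theta cells on average.

Problem sizes used by the test-suite recovery study: 28 pairs at hit rate
0.9 (25 successful epochs, matching the full design's expectation) so each
of the 400 runs stays under two seconds; the acceptance script samples the
same conditions at 10 seeds per frequency.

## Known limitations

* No ICA or channel interpolation: recordings with eye artifacts must be
  pre-cleaned; noisy channels can only be excluded.
* Re-referencing is not applied; recordings are analyzed as referenced.
* The 0.5 Hz grid bounds attainable precision; reliabilities near class
  boundaries can change class under small perturbations.
* Single-subject control runs report band shares only; the paired test
  needs ≥5 subjects.
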