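# Methods

This note records the models, parameter choices, and numerical decisions
behind `hfokit`, and what the simulation benchmark does and does not show.

## Detection model

The detector operates on the analytic-signal envelope of a bandpassed
channel. Two SD thresholds on the z-scored envelope play distinct roles:
the *onset* threshold (default 1 SD) delimits candidate clusters — maximal
runs of supra-threshold samples — and fixes the event boundaries at the
threshold crossings, with no post-hoc padding; the *inclusion* threshold
(default 5 SD) gates acceptance at the cluster peak. A third criterion
requires the cycle count measured inside the cluster boundaries to reach a
minimum (default 2.4). Cycle count and average frequency both derive from
the oscillation peaks of the bandpassed segment: average frequency is the
sampling rate over the mean peak-to-peak distance, and cycle count is the
event duration over the mean peak-to-peak interval, so the two are linked
by the identity `cycles = duration x frequency`. Peaks are strict local
maxima (first sample of a plateau); no prominence filter is applied, since
segments are already bandpassed and threshold-selected. A cluster whose
segment shows fewer than two peaks has no defined frequency and is
rejected.

Baseline normalization is one-pass: the mean and SD include any event
samples in the baseline window. With rare, brief events this biases the SD
upward only marginally; iterative event exclusion is deliberately out of
scope. In epoch mode each epoch is normalized independently, clusters are
found within each epoch, and a cluster touching an epoch edge is kept
as-is rather than merged across the boundary — the simplest semantics
consistent with per-epoch normalization. A trailing partial epoch is
normalized by its own statistics.

The single-threshold comparator implements the three-parameter scheme used
by RIPPLELAB's Hilbert detector: one SD threshold (default 3.5) on the
same per-epoch z-scored envelope, with runs shorter than a minimum
duration (default 10 ms) discarded. Its event boundaries are the crossings
of its own (higher) threshold, which is why its detected durations sit
systematically below the true burst durations and degrade faster with
noise than the two-threshold design, whose 1 SD boundaries hug the full
burst.

Cursor-guided detection restricts attention to clusters with any sample
within `search_range` (default 0.2 s — the concept comes from interactive
marking; the default is this package's choice) of the cursor; the nearest
cluster is qualified, with ties broken toward the earlier cluster for
determinism.

## Filtering

Both filter kinds are applied forward-backward (zero phase), so envelope
peak timing is preserved and effective attenuation doubles. The FIR kind
is a Hamming-window design of order `floor(3 * srate / low_cutoff)` (the
fractional quotient is floored; the tap count is made odd so the bandpass
has a well-defined passband). At 2000 Hz and an 80 Hz low edge this gives
75 taps and hence a transition band of roughly 87 Hz: tones near the low
band edge (e.g. 100 Hz) are only partially transmitted (two-pass gain
~0.73). This is a property of the prescribed short order, not a defect;
detection is unaffected because the envelope is z-scored, but absolute
in-band amplitudes near the edge are not preserved. The Butterworth kind
(4th order, applied as second-order sections) is essentially flat there.
Reflect padding of one filter length suppresses boundary transients. The
notch is a narrow zero-phase IIR notch (Q = 35) at 50 or 60 Hz; tones
20 Hz away pass within 5%.

## Spectrogram

The time-frequency map evaluates the Gabor wavelet (Gaussian-windowed
complex exponential, sigma = 6/eta per scale by default) by FFT
convolution, one frequency row at a time, kernels truncated at five
Gaussian SDs, with a 1/sqrt(s) normalization (s = 1/f). The default grid
is 60-500 Hz in 5 Hz steps — wide enough for ripple and fast-ripple work;
the grid, like the rest of the configuration, is user-settable. With the
default sigma factor the wavelet's frequency resolution is ~23 Hz SD, so
closely spaced tones blur; the click-averaging window (default 0.2 s)
trades noise suppression against temporal dilution, and a brief burst next
to a sustained background tone is better resolved with a shorter window
(0.05 s is used in the test suite's guided-detection scenarios). In
percentage mode the narrow band takes, on each side of the peak, the
*nearest* grid frequency at which the averaged spectrum has fallen to the
stated fraction of the peak; if it never falls that low on one side, the
grid end is used, and bands that end up empty or outside (0, Nyquist)
raise a degenerate-band error (guided detection then returns none with a
logged reason).

## Simulator

A simulated channel is the sum of twelve unit-amplitude sinusoids at 2.5,
6.0, 10.0, 16.0, 32.5, 67.5, 165.0, 250.0, 425.0, 500.0, 800.0 and
1500.0 Hz (random phases per dataset), sampled at 2000 Hz for 600 s by
default. Bursts at 100, 140, 180 and 220 Hz (20 per frequency, whole-cycle
counts drawn uniformly from 3-10) are inserted additively at uniformly
random, rejection-sampled onsets with at least 0.5 s separation. Noise is
white Gaussian, scaled so that clean-signal power over noise power equals
the requested SNR. The full benchmark suite is the noise-free condition
plus SNR 1-10 in unit steps, ten independent replicates each — 110
datasets; `generate_suite` yields them lazily because a materialized suite
is about 1 GB.

Burst amplitude defaults to 3x the background RMS. Burst edges carry a
raised-cosine (Tukey, taper fraction 0.25) ramp rather than a full Hann
window: the short ramp still prevents insertion-edge spectral splatter,
but keeps the envelope at its plateau over ~90% of the burst, so the
onset-threshold crossings recover nearly the full inserted interval and
the measured cycle count of a 3-cycle burst stays above the 2.4-cycle
acceptance minimum. (A full Hann taper shrinks the recovered interval to
~60% of the insertion, which would silently reject most 3-cycle events —
incompatible with near-perfect noise-free detection.) With these defaults
the noise-free suite is detected at >= 99% sensitivity by the default
detector configuration, which is the calibration the amplitude default is
chosen to satisfy.

What the simulator does *not* emulate: 1/f background spectra, spikes and
sharp transients, non-stationary artifacts, inter-channel structure, or
HFOs superimposed on epileptiform discharges. Passing the benchmark
therefore demonstrates correctness of the detection pipeline under the
stated synthetic conditions, not clinical performance on patient iEEG.

## Validation metrics

Matching is greedy, one-to-one, in start order, with >= 1 sample of
interval overlap — the most permissive rule consistent with "proportion of
inserted events detected". Sensitivity is matched truth over total truth;
the false-detection proportion is unmatched detections over total
detections (defined as 0 when nothing is detected); relative duration is
the detected/true duration ratio averaged over matched pairs. Per-condition
dispersion is the standard error across replicate datasets. On noise-free
data the peak-to-peak frequency estimate of a matched event is typically
within 5% of the inserted frequency; interference from the 165 Hz
background tone near tapered burst edges can push single events to ~6%.

## Problem sizes and determinism

The benchmark endpoints (10 replicates x 600 s at SNR 10 and SNR 1, both
detectors) regenerate in well under a minute; unit and property tests use
10-60 s datasets with proportionally fewer bursts, which exercise the same
code paths. The duration-consistency check runs the full 11-condition
sweep at 60 s with 20 bursts per dataset. All randomness flows through
numpy Generators seeded from explicit integers; dataset seeds derive from
a master seed, so every dataset, suite, and benchmark number is exactly
reproducible.

## File formats

EDF reading goes through MNE and returns microvolts; writing uses a
minimal 16-bit EDF writer (per-channel physical scaling, one data record
per second when the length divides evenly), so quantization error is
bounded by the per-channel range over 2^16. Event tables are tab-separated
with a fixed header; times appear as exact sample indices (0-based,
half-open intervals), as seconds from recording start (4 decimals), and as
wall clock derived from the recording start time. Sample indices make
write-then-read the identity on every field; floats are serialized with
full round-trip precision. The per-channel summary lists, for each of the
five event types (gamma, ripple, fastripple, ultrafast, spike), the count
and the total duration in seconds, plus totals, including all-zero rows
for event-free channels.
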