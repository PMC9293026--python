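# Methods

This note documents the models, rules and numerical choices implemented
in `erpkit`, the assumptions behind the synthetic-data generator, and
what the test suite does and does not establish about real data.

## Preprocessing model

Continuous 8-channel EEG (FPz, Fz, Cz, Oz, C3, C4, P7, P8; 500 Hz) is
analysed per condition family (checkerboards vs faces) in a fixed
order:

1. **Epoching** from −100 to 600 ms around each onset (351 samples at
   2 ms; window endpoints inclusive, sample *k* at t = −100 + 2k ms).
   3 s of real continuous context is kept on both sides for the
   filters; where the recording is too short the context is
   reflect-padded and the trial is logged. Epochs whose analysis window
   itself leaves the recording are excluded (reason `edge`).
2. **Band-pass** 0.1–40 Hz, 4th-order Butterworth applied
   forward-backward (zero phase, so peak latencies are not shifted; the
   magnitude response is squared). The skirt of this design is shallow:
   the two-pass gain at 50 Hz is −17.6 dB, which is why a dedicated
   line filter follows.
3. **Line filter**: for each of 50, 100, 150 Hz a sine/cosine pair over
   the padded segment is fit by least squares and subtracted. For a
   stationary sinusoid this cancellation is exact regardless of phase;
   tests pin the combined band-pass + line-filter residual of an 80 µV
   line component below 1 µV through the full pipeline.
4. **Baseline correction**: mean over −100..0 ms subtracted per
   channel; averages are re-baselined after trial averaging.
5. **Artifact flags** per trial × channel on the baseline-corrected
   epoch: *flat* when max |amplitude| ≤ 0.0001 µV; *amplitude* when any
   sample strictly exceeds ±150 µV. "Exceed" is read strictly in both
   directions, so a sample at exactly 150 µV is retained and a channel
   at exactly the flat threshold is flat; boundary tests pin this.
6. **Channel exclusion** when a channel is flagged in ≥80% of the
   family's trials (computed after filtering, before trial exclusion).
7. **Condition rules**: a checkerboard trial is excluded when Oz is
   flagged or bad; a face trial when P7 and/or P8 is.
8. **Re-referencing**, trial-wise: subtract Cz when Cz is unflagged,
   else mean(C3, C4) when both are unflagged, else exclude the trial
   (`no_reference`). Flags are computed once, on the pre-re-reference
   signal.

## Feature extraction

Features are computed on subject averages built from randomly drawn
clean-trial subsets (grids: checkerboards 10–50 and all; faces
10–100 and all, drawn with an equal upright/inverted balance;
per-orientation 10–60 and all). Draws are independent across trial
counts; each draw's seed derives deterministically from the master seed
and the (subject, session, condition set, n, stage) tuple via
`numpy.random.SeedSequence`, and is logged.

Peak identification scans the waveform for strict local extrema; a run
of equal samples counts once, peaking at the run's last sample when the
run is bounded by lower (higher) values on both sides — the two-sample
plateau case follows the rule that the second plateau sample is the
peak when the next sample deflects away. Endpoints are never peaks. The
component peak is the matching-polarity peak with the largest amplitude
in the polarity direction inside the window (ties: earliest); when the
window is empty it widens once by 20 ms per side (so P1's 50–200 ms
window becomes 30–220 ms); a still-empty window makes the component
invalid and its peak measures missing. A selected peak is vetoed as
baseline noise when its *point* amplitude does not strictly exceed the
largest same-polarity peak in the baseline window (point amplitudes are
used on both sides to avoid averaging across the baseline edge).

Amplitude measures: the peak amplitude of P1/N290 is the mean over a
60-ms window centred on the peak (clipped at the epoch edges); N290 and
P400 mean amplitudes are plain means over 190–350 ms and 300–500 ms.
P400 gets no peak measures — its morphology is too broad for stable
peak picking. Grand averages take individual all-trial averages with at
least 10 clean trials and a maximum absolute amplitude above 1 µV
(limited-signal screening).

## DTW direction

Both waveforms are cropped to the component window (P1 window for
checkerboards, N290 window for faces). Classic boundary-to-boundary DTW
with steps (1,0), (0,1), (1,1) and local cost |ref[i] − ind[j]|
(squared difference available as `dtw.metric: sq`); no global band —
the window crop already bounds the alignment. On accumulated-cost ties
the diagonal step is preferred, then the step advancing the individual
index, which makes the identity path unique so that
`direction(x, x) = 0` holds exactly. The statistic is
`Σ_path (j − i) / (N(N−1)/2)`; the normalizer is the number of lattice
cells under the diagonal, matching a statistic of 0 for the identity
path and the sign convention that a delayed individual waveform scores
positive. The reference is the same-condition-set grand average.

## Reliability

ICC(3,1) is computed from the two-way (subjects × sessions) ANOVA mean
squares; the 95% CI and one-tailed p (H1: ICC > 0) come from
F = MS_R/MS_E with (n−1, (n−1)(k−1)) df. Negative estimates are
reported as computed, never truncated. Band edges are implemented as
poor < .40 ≤ fair < .60 ≤ good ≤ .75 < excellent; the stated
".40 to .59" / ".60 to .75" convention leaves (.59, .60) and the point
.75 ambiguous, and the half-open reading above reproduces the labels at
their stated edges. All-identical scores leave the ICC undefined and
flagged rather than silently 0 or 1. Missing feature values are dropped
pairwise per (feature, trial count) cell, and each cell reports its
retained n.

Split-half consistency draws n clean trials at random and assigns
alternating draw positions to halves A and B; the ICC between A and B
features within a session is reported per trial count. Inversion
effects are upright − inverted per subject and session; their
reliability is the ICC of that difference across sessions, and the
condition effect itself is a two-sided paired t-test over subjects with
at least 20 clean trials per orientation (identical columns give t = 0,
p = 1; a nonzero constant difference leaves t undefined and flagged).

## Gaze validity

Interior gaps of ≤150 ms (measured anchor-to-anchor, inclusive) are
filled by linear interpolation; edge gaps have no anchor and stay
invalid. Looking time weights each sample by its inter-sample interval,
which is robust to irregular eye-tracker sampling. A trial is valid at
proportional looking ≥0.5 over the 0–500 ms stimulus window; session
attentiveness is the percentage of valid trials among presented trials,
and a participant is "highly attentive" when both sessions reach 60%
(inclusive). When screen bounds are configured, validity additionally
requires on-screen coordinates; otherwise the eye-tracker's validity
flag alone decides.

## Synthetic-data generator

The simulator emulates the study conditions the pipeline targets:
sessions of 72 checkerboard and 72 + 72 upright/inverted face trials at
500 Hz (1.25 s onset spacing, 4 s lead-in/out so the 3 s filter padding
uses real context), with:

* **Component morphology**: Gaussian bumps. Defaults — P1 at Oz,
  +8 µV, 120 ms, width 20 ms; N290 at P7/P8, −6 µV, 260 ms, width
  25 ms; P400 at P7/P8, +5 µV, 420 ms, width 55 ms. The N290/P400
  placement keeps the overlap of the two opposite-polarity bumps small
  enough that neither shifts the other's extremum by more than one
  sample, so injected latency is a valid truth for peak recovery.
  Inverted faces get a +1.5 µV P400 offset by default (a face-inversion
  effect of realistic size).
* **Latent variance model**: each component's latency and amplitude are
  drawn per subject (between-subject SD) and then per session
  (within-subject SD; trial-level jitter is zero by default), so the
  true test–retest ICC of each parameter is analytic:
  sd_b²/(sd_b² + sd_w²). Defaults put latency ICCs at 0.80 and
  amplitude ICCs near 0.7.
* **Noise**: independent 1/f (exponent 1) background per channel,
  default 20 µV RMS per trial — a level at which tens of trials are
  needed for stable averages, as in toddler EEG. A 0.5 µV common-mode
  6 Hz background is always added to every channel: it keeps signal-free
  channels from triggering the flat-signal rule in noiseless runs and
  cancels exactly under re-referencing, so noiseless epochs still equal
  the pure kernel sum.
* **Artifacts**: per trial × channel, with probability
  `artifact_rate_amp` (default 0.05) a ±250 µV Gaussian bump is added
  inside the epoch; per channel × session, with probability
  `artifact_rate_flat` (default 0.02) the channel is zeroed for the
  whole session. All placements are logged in the truth record, so the
  flag set is exactly predictable at low noise.
* **Gaze**: 60 Hz streams with alternating valid/invalid runs of
  geometric length (mean valid run 2 s; invalid-run mean set so the
  long-run invalid fraction equals `gaze_gap_rate`), exercising both
  the ≤150 ms interpolation and the 50% looking rule.

Everything derives from one seed through `SeedSequence`; identical
seeds give bit-identical sessions.

**What the simulator does not model**: realistic head-volume
conduction, blink/EMG waveform shapes, habituation across repeated
stimuli, non-Gaussian component morphology, or correlated noise across
channels. Passing tests therefore establish that the *rules* are
implemented exactly and that parameter recovery and reliability
estimation behave correctly under a known generative model — not that
the defaults reproduce any particular empirical dataset.

## Verification strategy and problem sizes

Every algorithmic rule has an independent oracle in the test suite:
peak detection against exhaustive enumeration of all length-6 sequences
over {−1, 0, 1} and random longer sequences; DTW minimal cost against
full path enumeration at small N and the identity/antisymmetry/sign
properties; ICC(3,1) against an explicit sums-of-squares oracle and the
`pingouin` implementation; the paired t against explicit sums and
scipy; filters against their designed transfer functions and exact
least-squares cancellation; artifact bookkeeping against a hand-counted
10-trial fixture with boundary cases.

Monte-Carlo checks use score-matrix-level simulation (the same latent
draw the cohort simulator uses): ICC recovery at n = 200 subjects (50
replicates per true ICC in {0.2, 0.5, 0.8}) and CI coverage at n = 30
(500 replicates). Full-EEG checks use noiseless two-subject,
two-session cohorts at the study's full trial budgets for feature
recovery, and small noisy cohorts (3–12 subjects, reduced budgets) for
the end-to-end pipeline; these sizes keep the default suite fast while
exercising every stage.

## Known limitations

* EDF files are read (via mne) but not written; the delimited-text
  dialect is the repository's round-trip format. No writer for EDF is
  bundled, so the EDF path is exercised only against malformed input.
* The ICC's p-value is one-tailed (H1: ICC > 0); two-tailed users
  should double it.
* The DTW statistic is computed without a global path constraint; for
  pathologically non-overlapping waveforms the warping path (and hence
  the direction sign) is driven by amplitude structure, not latency
  alone.
* `inclusion_rates` summarizes session-0 clean-trial counts; multi-site
  or >2-session designs are out of scope (k = 2 throughout).
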