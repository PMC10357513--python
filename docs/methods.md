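# Methods

## The synthetic stated world

No recordings for this haptic-augmented emotion paradigm are publicly
available, so the analysis runs on a generator whose defaults encode the
experimental protocol: 16 subjects, 16 sessions each (4 per emotion), a 5-s
cue before every clip, nominally 4-min clips at 1,000 Hz on 63 usable
channels (FCz online reference, Fpz ground), haptic stimulation only in the
clip's second half, and a balanced 8/8 split between the two haptic
patterns (additionally 2/2 per emotion, without which per-pattern 4-class
evaluation could lose a class entirely). Desk-scale runs shrink clip length
and sampling rate only; the statistical structure is untouched
(`scaled_config`).

### Signal model

Each channel is a sum over the five canonical bands of band-limited
Gaussian noise: white noise filtered by an order-4 Butterworth bandpass,
rescaled by the filter's analytic white-noise energy gain (mean |H|⁴ over
the Nyquist range, since the synthesis filter is applied forward–backward)
so the target variance is exact in expectation rather than pinned per
realization. Background variances are 20/12/10/6/4 µV² for δ/θ/α/β/γ — a
coarse stand-in for the 1/f power gradient. This is deliberately the
*minimal* model under which variance-based features carry the class signal:
no volume conduction, no true 1/f continuum, no non-Gaussian microstructure
(which has one knock-on effect on ICA, below).

Emotion classes multiply the variance of discriminative (channel-group,
band) components inside the clip. The default gains are lateralized —
approach emotions lean left, withdrawal emotions lean right — so that the
hemispheric-asymmetry features (DASM) also carry class information:

| emotion | temporal L/R β | temporal L/R γ | prefrontal L/R β | prefrontal L/R γ |
|---------|---------------|---------------|-----------------|-----------------|
| joy     | 1.6 / 1.4     | 2.8 / 2.2     | –               | –               |
| sadness | –             | –             | 2.0 / 2.4       | 1.6 / 2.0       |
| fear    | 2.0 / 2.4     | 1.6 / 1.6     | –               | 1.4 / 1.4       |
| neutral | –             | –             | –               | –               |

Per session, each bilateral region/band draws one lognormal amplitude
jitter (σ = 0.15 in log space) shared between hemispheres, so asymmetry
ratios are stable within a session while session means scatter — this
between-session variability is what keeps session-grouped cross-validation
honest. The jitter scale was fixed a priori so per-pattern DE accuracies
land in the 80–95 % range reported for comparable real paradigms; larger
jitter (0.25) pushed them 10–20 points lower.

The haptic half multiplies each class deviation by the **separation gain**
g ≥ 1: a component with non-haptic multiplier m becomes 1 + (m − 1)·g, so
g = 1 leaves the halves exchangeable (tested), and neutral sessions are
never modulated. Default g = 1.5. On top: a 50 Hz common-mode sinusoid
(5 µV) and a single low-frequency burst source (60 µV, ~0.8-s Hanning
bursts at 0.1 Hz) projected onto the six prefrontal channels with fixed
weights — a rank-1 EOG surrogate that ICA can isolate.

What a green test therefore establishes: the pipeline recovers class
structure, haptic amplification, and topography *of this model*. It says
nothing about non-stationary rhythms, evoked transients, cross-channel
correlation structure, or artifacts beyond line noise and rank-1 EOG.

### Haptic schedules

Pattern 1 is the fixed scheme (joy 1.4 Hz at 90 %, sadness 0.45 Hz at 50 %,
fear 0.5 Hz at 90 %; discrete 0.2-s pulses; no row exists for neutral, so
neutral/pattern-1 sessions carry an empty schedule). Pattern 2 maps a
volume trace to intensity through a clipped affine function — zero at or
below a silence threshold (default: the trace's 30th percentile), then
rising from i_min = 30 % to i_max = 100 % at the trace maximum — with
consecutive above-threshold samples merged into events. Volume traces are
smoothed rectified noise with carved-out silences so the threshold rule is
exercised. The vest's 5×4 motor matrix is collapsed to one global intensity
channel. The schedules document the stimulus; in the signal model the
haptic effect enters only through the separation gain.

## Preprocessing

Order: resample (polyphase, anti-aliased, downsampling only) → 50 Hz notch
(Q = 30, zero-phase) → 1–50 Hz bandpass (order-4 Butterworth, zero-phase) →
ICA → common average reference → segmentation. Rationale for deviations and
tie-breaks:

- **Band filters, order 6.** The five narrow bands share corner
  frequencies; at order 4 the forward–backward corner loss drops ~11 % of
  total variance, breaking the requirement that the five band variances sum
  to the broadband variance within 10 %. Order 6 keeps the loss at ~9 %.
  The broad 1–50 Hz filter stays order 4.
- **ICA.** FastICA with a fixed seed; components whose |correlation| with
  the Fp1/Fp2 mean exceeds 0.8 are zeroed. Because the synthetic background
  is Gaussian, full FastICA convergence is impossible *in principle*
  (Gaussian sources are unidentifiable), so the max-iteration estimate is
  used for rejection — as EEGLAB's runica effectively does — with a warning
  and a `converged: False` flag; only a hard decomposition failure passes
  the input through. The stage can be disabled (`run_ica=False`), which the
  heavy statistical tests do: it is orthogonal to effect recovery and
  dominates runtime.
- **CAR with reference recovery.** Data referenced to FCz implicitly
  contain FCz as a zero channel; it is appended before subtracting the
  per-sample mean across all 64 channels. This both makes the channel mean
  exactly zero (idempotently) and yields a proper FCz signal, which the
  caudality pair FCz–CPz requires.
- **Baseline.** The 5 s before each clip are attached to every segment and
  used only in the topographic stage (baseline-subtracted DE); the time
  series itself is not baseline-corrected.
- CB1/CB2 are part of the canonical montage (the generator emits them); if
  an input recording lacks a pair-table channel the affected pairs are
  dropped with a warning rather than failing the run.

## Features

DE uses the natural logarithm, so the unit-variance Gaussian closed form
½ ln(2πe) ≈ 1.4189 nats holds exactly; the estimator is the sample variance
of the band-filtered 1-s window (at n = 200 the log-variance bias is
≈ −0.0025 nats, negligible against the ±0.05 acceptance band). Zero-variance
windows are floored at σ² = 1e−30 to stay finite. The spectral route —
log mean in-band periodogram energy of the 200-sample window Hanning-tapered
and zero-padded to 256 — is kept as the independent oracle; the two routes
are affine with R² > 0.99 per band on stationary inputs (tested). PSD's
"average energy" is the mean of one-sided periodogram values across in-band
bins (bin edges inclusive). Windows are non-overlapping; each window is one
classifier sample by default (`average_windows` collapses sessions to their
mean — absolute accuracies are sensitive to this choice, which is the main
reason absolute levels are not comparable across studies). No temporal
smoothing (no LDS) is applied.

## Classification

Linear-kernel SVM, C = 1, features standardized with training-fold
statistics. Folds are grouped by session and stratified by dealing each
class's sessions round-robin across folds; with 8 sessions per pattern
(2 per class) this guarantees every training fold retains all four classes,
and windows never leak across the split. **One-vs-one, not one-vs-rest:**
with 12-vs-36-window binary subproblems per fold, OvR collapsed to 50–66 %
on single-band data whose class structure is linearly separable by
construction, while libsvm's OvO decomposition (the field's de-facto
default) recovered it; OvO is therefore the package's choice. Per-subject
accuracies are averaged across subjects for the report tables.

## Statistics

Two-sided paired-sample t-tests on per-subject accuracies per (feature,
band, pattern) cell, α = 0.05, df = n − 1; zero-variance differences are
flagged degenerate rather than scored. No multiple-testing correction by
default (an optional Holm adjustment exists). Growth is computed per
subject as (haptic − non-haptic)/non-haptic × 100 and then averaged — the
aggregation that makes a growth table internally consistent, even though
published tables of this kind are typically not exactly recoverable from
their companion accuracy means; no attempt is made to match any particular
printed value. Growth is undefined (NA) when a baseline accuracy is ≤ 0.

## Spectral summaries

Morlet wavelet (7 cycles, L2-normalized kernel, 40 log-spaced frequencies
1–50 Hz) squared-magnitude energy, averaged in non-overlapping 5-s windows,
optionally channel- and subject-averaged; energy is averaged first and any
log scaling is left to display. Topographies are window-mean DE minus
window-mean baseline DE per channel and band; scalp maps interpolate those
values with a thin-plate-spline RBF on the unit-disc head model (electrode
values reproduced exactly, NaN outside the head circle). 2-D electrode
coordinates are a standard azimuthal-equidistant projection (outer 10 %
ring at r = 0.8; FT9/TP9/CB-row at r = 1.0; inner electrodes interpolated
along their row), shipped as a plain-text table.

## File formats

BrainVision (INI-style vhdr, vmrk markers, multiplexed IEEE float32 data)
and EDF (16-bit, one data record per sample so any length is representable;
physical ranges digitized against the 8-character header representation so
read-back scaling is exact to one LSB). Plain EDF has no annotation
channel; events round-trip through a `<stem>.events.csv` sidecar rather
than EDF+ TAL framing. Event onsets are written at sample resolution; the
generator emits sample-aligned onsets, so round-trips are exact.

## Known limitations

- Absolute accuracies depend on windows-as-samples vs session-averaging
  and on session-grouped folding (stricter than window-level shuffling);
  only orderings and contrasts are meaningful.
- DASM/DCAU accuracies are structurally lower than PSD/DE here because the
  generator's asymmetry signal is a small log-ratio on few pairs.
- The ICA stage is an automated stand-in for manual component review and
  is validated only against the rank-1 EOG surrogate.
- `GeneratorConfig` at full scale (1 kHz, 4-min clips, 16 subjects) needs
  several GB of memory per subject; use `scaled_config` on a laptop.
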