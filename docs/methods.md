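# Methods

This note documents the models, defaults and numerical conventions behind
`ictrain`, and what the synthetic-data generators do and do not emulate.

## Training game engine

A game is 30 trials. At the start of each game the Go proportion `p` is
drawn uniformly from [0.70, 0.90] and the Go count fixed to
`round(p × 30)`; drawing a fresh `p` every game prevents players from
pre-preparing responses from stimulus statistics, and realizing it as an
exact count keeps per-game scores comparable. Stop trials take a
configurable share (default 0.10) of the non-Go allotment, with the
healthy→unhealthy change latency drawn uniformly in [100, 300] ms (clipped
inside the deadline); the remainder are plain Nogo trials. Trial order is a
uniform permutation.

Adjudication is a pure function of (trial kind, response latency): a Go tap
within the deadline is `correct_go`; late or absent Go taps are omissions;
any tap on an image that is unhealthy at tap time is a `commission`;
withholding on unhealthy images is `correct_inhibit`. Latencies up to
300 ms past the deadline (the *grace* window) are recorded as late misses;
anything beyond is rejected as malformed input.

**Difficulty staircase.** The deadline schedule is
`rtd(level) = max(250, 1000 − 50·(level − 1))` ms and the image count is
`min(level, 12)`. Levels never decrease. Promotion after a game requires
all of: accuracy ≥ 85%, at least one correct inhibition, and mean
correct-Go latency ≤ 0.65 × the current deadline. The speed criterion is a
deliberate design choice: with a monotone staircase, promoting on accuracy
alone eventually pushes a player onto a deadline they cannot beat and
parks them there, so correct-Go counts *fall* late in training. Requiring
comfortable speed at the current level makes the staircase converge to a
level the player can actually sustain, which reproduces the empirically
expected course signature (reaction time down, correct Go and correct Nogo
counts up across session blocks).

**Log analysis.** A course targets 10 games/day for 14 days (140 games);
participants with fewer than 90 games are excluded (the 65% adherence
cutoff). A retained log is split into k = 3 equal consecutive session
blocks (remainders to the earliest blocks: 91 games → 31/30/30) and each
block is summarized by per-game means. Summaries are per game, not per
day; any count-like column therefore has a 0–30 range.

## Simulated players

An agent is a response policy, not a cognitive model: Go latencies are
truncated-normal (truncation at 100 ms and at deadline + grace), omissions
and commissions are Bernoulli, and learning is per-game geometric decay of
the latency mean, the commission probability and the omission probability,
each with a floor. The `learner` preset (rt 430 → floor 295 ms at rate
0.9975/game; p_commission 0.70 → 0.05 at 0.985; p_omission 0.25 → 0.02 at
0.98) was chosen so a 140-game course lands near the empirically typical
session means (~400 ms falling to ~310 ms) and shows the correct direction
on all three performance measures; the package treats direction, not the
printed counts, as the calibration target because the aggregation unit of
published per-session counts is ambiguous. On stop trials the sampled
latency decides the regime: a draw earlier than the change latency is an
ordinary Go tap; a later draw is emitted only on an inhibition failure.

## Auditory Go/Nogo assessment

Tasks are symbolic (no audio I/O): 1100/2000 Hz tones, 200 ms, ISI 2500 ms
("longer" deadline variant) or 1250 ms ("shorter"). Sequences are
exact-count (exactly 70 Go in 100 trials), uniformly ordered, with onsets
at k × ISI. Ten practice trials can be generated but are never scored or
epoched. Tone assignment and task order are counterbalanced by cycling the
four (tone × order) cells across participants with a per-session rotation,
giving ±1 balance for any roster size. A press is attributed to the most
recent onset within (0, ISI]; the ISI is the de facto response deadline, a
convention covering the unstated case of presses during the tone itself.
Only the first press per trial counts, so scoring is invariant to
permutations of the press stream.

## EEG synthesis

Recordings are generated already referenced, in µV, at 500 Hz (a
sampling-rate choice; all windows are specified in ms and rounded to the
nearest sample). Background noise is AR(1) with coefficient 0.95, scaled
to a stationary SD of 3 µV — low-frequency-dominant like real EEG, but
without line noise, drift or alpha rhythm. Each stimulus adds two Gaussian
bumps: a frontal-maximal negativity (N2-like; peak 250 ms, FWHM 45 ms,
Fz −6 µV) and a parietal-maximal positivity (P3-like; peak 420 ms, FWHM
80 ms, Pz +10 µV), with 8 ms trial-to-trial latency jitter and a 1.3× gain
on Nogo trials (inhibition-enhanced components). Blinks are a Poisson
process of 150 ms-wide bumps, 180 µV at VEOG, propagating to scalp rows at
gains 0.7/0.3/0.1 (frontal/central/parietal) — by construction large
enough (126 µV frontally) to trip the ±100 µV epoch screen, which is what
makes rejection testable by injection. What the generator does *not*
emulate: volume-conduction mixing, muscle artifact, electrode drift/pops,
impedance effects, or any dependence of the evoked response on behavior.
Passing pipeline tests therefore demonstrate correctness of the
*processing*, not robustness to every real-world artifact class.

## ERP quantification chain

Processing order: zero-phase low-pass → epoch → baseline-correct → reject
→ average → peak measurement.

- **Filter**: 4th-order Butterworth applied forward-backward
  (`filtfilt`). Because two passes square the magnitude response, the
  design cutoff is widened analytically (Wn = f_c / (10^(3/20) − 1)^(1/8)
  ≈ 26.8 Hz for f_c = 24 Hz) so the *realized* response is −3 dB at 24 Hz;
  a naive Wn = 24 Hz design would be −6 dB there.
- **Epochs**: −100..+900 ms as half-open sample intervals after ms→sample
  rounding (500 samples at 500 Hz). Events whose window leaves the
  recording are dropped with a warning. Baseline correction subtracts the
  per-channel mean over [−100, 0) ms — the field-standard reading of a
  100 ms prestimulus window.
- **Rejection**: an epoch is excluded iff any *scalp* sample exceeds
  ±100 µV (strict inequality; exactly ±100 is kept). EOG channels never
  trigger rejection — blinks are caught via their scalp propagation.
  Rejection is monotone in the threshold, and accepted + rejected = total.
  An optional high-variance segment mask (`erp.high_variance_mask`)
  provides an automated continuous-data screen in place of manual visual
  artifact marking; it is off by default because the epoch rule is the
  primary gate.
- **Averaging**: point-wise mean over accepted epochs of one condition
  (correct Go / correct Nogo); grand means are unweighted across
  participants.
- **Peaks**: N2 latency is the argmin at Fz within 190–300 ms, P3 the
  argmax at Pz within 300–580 ms; ties break to the earliest sample, and
  an extremum on a window endpoint is flagged (`boundary_peak`) rather
  than silently accepted. Amplitudes at all nine sites are read at exactly
  the reference latency. The locking site and the analysis/reporting site
  are independent settings (`lock_site`), since latency analysis may be
  restricted to a frontal site while P3 quantification locks parietally.

## Statistics

All sums of squares are classical balanced-design decompositions on
complete cases; participants missing a time point are dropped with a
logged count (this matches designs whose error dfs vary by outcome, e.g.
df2 = 46, 48 or 50 for nominal N = 52). One-way ANOVA from summary
statistics (means, SDs, ns) is algebraically identical to the raw-data
path — it exists so baseline tables published only as summaries can be
re-derived; with 1-dp rounded inputs the reconstructed F carries roughly
±10% relative rounding error. Two-level within effects and planned
adjacent contrasts are squared paired t tests with df (1, n − 1).
Sphericity correction for the 3-level repeated factor is available
(Greenhouse–Geisser) but off by default, matching the convention of
reporting uncorrected dfs. No multiplicity correction is applied; α is
.05 throughout.

The generic `factorial_mixed_anova` handles any number of within factors
over one between factor on complete, group-balanced data: effect sums of
squares come from inclusion–exclusion on cell-mean tables, and each
within-term's error is its interaction with subject(group), obtained by
recursive residual decomposition. It is validated against statsmodels
`AnovaRM` (pure within designs) and `pingouin.mixed_anova` (one within +
between). Degenerate cases are explicit: zero effect and zero error yields
F = 0 with a `degenerate` flag; nonzero effect with zero error yields
F = ∞, p = 0, flagged.

Power for the dependent-means t test iterates n upward and evaluates the
exact noncentral-t tail power at δ = d√n, df = n − 1; the returned n is
the smallest meeting the target (cross-validated by 10⁵-replicate Monte
Carlo in the test suite).

## Cohort simulator

Outcomes are drawn bivariate-normal per participant across the two time
points, with per-cell (condition × time) means/SDs and a test–retest
correlation of 0.6 — the simplest model supporting the paired structure
the split-plot ANOVA assumes. Default cells encode the outcome pattern of
a successful training arm (healthy-eating score and cognitive restraint
rising, unhealthy taste-test kcal falling) against a drifting waitlist
arm; where a published source gives conflicting directions for the
taste-test healthy-food cells, the defaults follow the textual account
(increase after training). Demographics are truncated normals (age ≥ 18;
BMI ≥ 25, mean 29.54, SD 4.05). Energy densities (nuts 6.07, grapes 0.69,
chips 5.36, candy 4.92 kcal/g) are configurable constants typical of
nutrition tables, not asserted study values. HEQ/TFEQ item keys are
editable placeholders (round-robin item→subscale assignment, uniform
weights) because the instruments' proprietary keys are not public;
subscale-level simulation is the default path and item-level scoring is a
scaffold.

## End-to-end run and problem sizes

`run_study` seeds three independent substreams (cohort, training,
assessment/EEG) from the run seed, so runs are bit-reproducible and stages
re-runnable in isolation. Defaults: 26 participants per arm for the
cohort; a 140-game target with 15% of simulated participants dropping out
below the 90-game cutoff; and 6 participants per arm in the EEG subsample
(2 sessions × 2 task variants each, 100 trials per task) — a deliberately
modest ERP subsample that keeps a full run around half a minute while
still exercising the four-way amplitude ANOVA. The ERP ANOVA uses complete
cases trimmed to equal group sizes, as the balanced factorial routine
requires. The manifest records the config hash, seed and library versions
needed to reproduce a run exactly.

## Known limitations

- Agents are policies, not process models; they cannot address questions
  about mechanism (e.g. evidence accumulation, proactive vs reactive
  inhibition).
- The EEG generator's artifact repertoire is blinks only; rejection-rate
  realism under muscle or movement artifact is untested.
- `factorial_mixed_anova` requires complete, group-balanced data and
  applies no sphericity correction to multi-level within factors.
- The staircase never demotes; sustained late-course performance collapse
  (fatigue) would not be reflected in level.
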