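# ictrain

A simulation and analysis toolkit for mobile **inhibitory-control (IC)
training** studies in the food domain: the kind of randomized
waitlist-control trial in which overweight adults play a daily go/nogo +
stop-signal game on their phone (tap healthy foods fast, withhold to
unhealthy foods), and training efficacy is assessed with eating-behavior
instruments, a laboratory taste test, an auditory Go/Nogo task, and
event-related potentials (ERPs).

The package is aimed at researchers who want to prototype, power and
validate such a trial end-to-end before collecting data. Every stage is
implemented headlessly and exercisable on synthetic data:

- **Training game engine** (`ictrain.engine`) — 30-trial games with the Go
  proportion redrawn uniformly in [0.70, 0.90] per game, stop trials whose
  image turns unhealthy mid-countdown, a monotone difficulty staircase
  (shorter reaction-time deadlines, up to 12 simultaneous images), per-game
  performance logging, the 90-game adherence cutoff and equal-thirds
  session splitting (e.g. games 1–40 / 41–80 / 81–120).
- **Simulated players** (`ictrain.agents`) — truncated-normal latencies,
  Bernoulli inhibition failures, geometric learning with floors; presets
  `static`, `learner`, `fast-guesser`.
- **Auditory Go/Nogo assessment** (`ictrain.assessment`) — 100 trials,
  exactly 70% Go; 1100/2000 Hz tones, 200 ms, ISI 2500 ms (longer deadline)
  or 1250 ms (shorter); tone/order counterbalancing; behavioral scoring.
- **ERP pipeline** (`ictrain.eegsim`, `ictrain.erp`) — synthetic 9-site EEG
  (F3/Fz/F4, C3/Cz/C4, P3/Pz/P4 + EOG) with embedded N2/P3 components and
  blink artifacts; zero-phase low-pass (−3 dB at 24 Hz), epochs −100..900 ms,
  baseline correction, ±100 µV rejection, per-condition averages, and
  reference-locked peak measurement (N2: largest negativity at Fz in
  190–300 ms; P3: largest positivity at Pz in 300–580 ms; amplitudes at all
  sites read at the reference latency).
- **Statistics** (`ictrain.stats`) — one-way ANOVA from raw data *or* from
  printed summary statistics, the time × condition split-plot ANOVA with
  simple effects, repeated-measures ANOVA with adjacent planned contrasts,
  a generic balanced mixed-factorial routine for multi-way ERP designs,
  partial η², and dependent-means power analysis.
- **Cohort simulator** (`ictrain.cohort`) — two-arm cohorts with bivariate
  normal (time 1, time 2) outcomes per participant, taste-test calorie
  scoring (grams × energy density), questionnaire scoring scaffolds.

## The statistics at the core

For any tested effect the engine reports `F`, `(df1, df2)`, `p` and partial
eta squared,

```
η²ₚ = F·df1 / (F·df1 + df2),
```

the effect-size identity that links every reported ANOVA triple. The
split-plot (mixed) design crosses a between-subjects factor (condition:
training vs waitlist) with a within-subjects factor (time 1, 2); on
complete balanced data the interaction has df (1, N − 2). Sample-size
planning for a dependent-means t test finds the smallest n whose
noncentral-t power

```
power(n) = P(|T| > t₀.₉₇₅,ₙ₋₁),   T ~ nct(df = n−1, δ = d·√n)
```

meets the target; for d = 0.5, two-tailed α = .05 and 95% power this gives
n = 54.

## Worked example

Find the required sample size, then simulate and analyze two training
courses:

```
$ ictrain power --d 0.5
n = 54 (achieved power 0.9502)

$ ictrain simulate-training --n-participants 2 --seed 1 --out log.csv
wrote 280 game records to log.csv

$ ictrain analyze-log --log log.csv --out sessions.csv
2/2 participants meet the 90-game cutoff
wrote session summaries to sessions.csv

$ head -4 sessions.csv
participant_id,session,n_games,mean_rt_ms,mean_correct_go,mean_correct_nogo,mean_errors,mean_omissions,mean_level
P001,1,47,404.29426080573376,19.78723404255319,3.276595744680851,3.106382978723404,3.8297872340425534,3.3617021276595747
P001,2,47,359.5216225853328,22.638297872340427,4.340425531914893,1.446808510638298,1.574468085106383,11.063829787234043
P001,3,46,321.9969078622339,23.23913043478261,5.239130434782608,0.6086956521739131,0.9130434782608695,12.173913043478262
```

The session rows show the signature of a learning player: mean reaction
time falls (404 → 322 ms), correct Go and correct Nogo counts rise, error
and omission counts fall, and the game level climbs toward the 12-image
maximum. `ictrain run-study --seed 1 --out run/` executes the whole trial —
cohort, training arm, assessment + EEG at both time points — and writes
tidy ANOVA tables plus a manifest sufficient to re-run it bit-identically.

Other subcommands: `simulate-assessment`, `simulate-eeg`, `erp-quantify`,
`simulate-cohort`, `rct-stats` (see `ictrain --help`).

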