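# antiphon

Turn-taking analysis for interactive acoustic playback experiments with
vocally responsive animals.

In an interactive playback trial, an operator broadcasts a recorded call
(the *exemplar*) and adapts the timing of subsequent broadcasts to the
subject's answers. The scientific questions are temporal: did the subject
engage in vocal turn-taking (antisynchrony), did its response latencies
track the behavioral phases of the encounter, and did it entrain to the
playback's rhythm like a coupled oscillator? `antiphon` implements the full
analysis chain for such an exchange — built around a single ~20-minute
humpback whale "whup" call exchange design (one subject, alternating
exemplar/subject timeline, blind-observer phase annotations) but applicable
to any annotated two-party call exchange.

## What it computes

Given time-ordered call events (onset, offset, source, optional amplitude),
behavior events (blows, surfacings) and behaviorally defined phase
intervals:

- **Inter-call latency**: for consecutive same-source calls,
  `latency = onset(next) − offset(previous)`; latencies are stratified by
  phase (of the terminating call) and by recording day
  (control vs playback).
- **Counter calls**: a subject call is a counter call iff the most recent
  prior call is an exemplar and no blow/surfacing falls between that
  exemplar's offset and the call's onset.
- **Latency-ratio matching**: each answered call yields a response pair —
  the latency *into* the call versus the latency *out of* it. The two
  latencies standardize to percentage shares of their total
  (`share_small = 100·min(L₁,L₂)/(L₁+L₂)`); a pair is *matched* when the
  split lies between 41:59 and 50:50 (inclusive), and its *discrepancy* is
  the absolute share difference `100 − 2·share_small` in percentage points
  (0 = perfect temporal match).
- **GLM contrasts**: negative binomial regression (log link, ML dispersion,
  Poisson fallback) for whole-second latencies and integer discrepancies,
  logistic regression for matched-vs-not (with a Haldane–Anscombe corrected
  2×2 table under separation), Gaussian regression for amplitude trends.
- **Randomization tests**: predictor labels are permuted (N = 1,000 by
  default), the coefficient recomputed per permutation, and the empirical
  two-sided p-value reported as `(1 + #{|β*| ≥ |β_obs|}) / (N + 1)`.
- **Synthetic sessions**: a generator with phase-dependent Gamma response
  latencies, probabilistic latency coupling to the operator's preceding
  broadcast latency, a mirroring or fixed-mean operator, scheduled blows
  that delay and de-classify answers, an amplitude decline toward
  disengagement, and a sparse control-day sequence — with full ground truth
  for parameter-recovery testing.

## Worked example

Simulate a 20-minute exchange with the default (three-phase) scenario and
analyze it end to end:

```bash
antiphon simulate --preset paper_like --seed 42 --out demo
antiphon analyze \
    --calls demo/calls.tsv --behavior demo/behaviors.tsv \
    --phases demo/phases.tsv \
    --control demo/control_calls.tsv --control-phases demo/control_phases.tsv \
    --seed 42 --out demo/report.json
```

which prints (abridged):

```
latency records: 36
counter calls:   25
E-T pairs: 24   T-E pairs: 28

Match counts by phase (E-T):
        phase  n_pairs  n_matched  n_unmatched  sufficient
    AGITATION       11          6            5        True
DISENGAGEMENT        1          0            1       False
   ENGAGEMENT       12         12            0        True

Latency ~ phase/day [NEG_BINOMIAL/LOG, n=36, ref=AGITATION]
           CONTROL: beta=+0.712  se=0.142  p=5.132e-07
     DISENGAGEMENT: beta=+0.636  se=0.143  p=8.442e-06
        ENGAGEMENT: beta=-0.202  se=0.116  p=0.08041

Latency ~ counter call [NEG_BINOMIAL/LOG, n=36, ref=NOT_COUNTER]
           COUNTER: beta=-0.796  se=0.094  p=3.323e-17

Matched ~ phase [LOGISTIC/LOGIT, n=23, ref=AGITATION]
        ENGAGEMENT: beta=+3.052  se=1.554  p=0.04958

Amplitude trend [GAUSSIAN/IDENTITY, n=32, ref=(slope)]
          time_min: beta=-0.920  se=0.070  p=4.614e-14

Randomization (1000 permutations, seed 42): beta_obs=-0.796, p_empirical=0.0010
```

Reading the output: engagement-phase latencies are shortest and control-day
latencies longest (positive `CONTROL` log-mean-ratio against the agitation
reference); counter calls come ~55% faster than non-counter calls
(`exp(−0.796) ≈ 0.45`), and the permutation test confirms the contrast is
not an artifact of the small sample (p = 0.001); every engagement-phase
pair matched the operator's rhythm versus 6/11 in agitation (odds ratio
`exp(3.05) ≈ 21`); the disengagement phase contributed a single pair and is
flagged insufficient, excluded from inference; call amplitude declined by
0.92 dB/min as the subject departed. All of this mirrors the generator's
ground truth, which is written alongside the tables as
`demo/ground_truth.json`.

The same machinery is available as a library:

```python
from antiphon import PlaybackExchangeModel, read_selection_table, Session

calls = read_selection_table("selections.txt", dialect="RAVEN")
session = Session(calls=calls, behaviors=[...], phases=[...])
results = PlaybackExchangeModel(session).fit(n_randomizations=1000, seed=1)
print(results.summary())
```

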