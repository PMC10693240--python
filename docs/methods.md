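# Methods

This note documents the statistical procedures `antiphon` implements, the
assumptions they rest on, the design choices made where a convention had to
be fixed, and the limits of what the synthetic-data tests establish.

## Event model and conventions

A session is a time-ordered set of call events (source EXEMPLAR or SUBJECT,
onset/offset in seconds from session start, optional relative amplitude in
dB), behavior events (neutral blow, wheezy blow, surfacing, other) and
non-overlapping phase intervals. Conventions that the data formats leave
open were fixed as follows:

- **Phase intervals are half-open `[start, end)`**, so every instant maps
  to at most one phase and boundary times are assigned uniquely.
- **Latency-record phase is the terminating call's onset phase**: the
  response is the event being explained.
- **Unphased calls** (outside every interval) are excluded from
  phase-stratified contrasts but retained in whole-series analyses such as
  the counter-call contrast.
- **Overlapping same-source calls** (negative computed latency) are dropped
  with a warning rather than clamped to zero; annotation error is the
  likelier cause.
- **Counter-call rule**: a subject call counts as a direct exchange iff the
  most recent prior call is an exemplar and no blow or surfacing falls in
  the open interval from that exemplar's offset to the call's onset.
  Behavior kinds other than blows/surfacings do not break an exchange,
  because the exclusion is motivated by breathing interrupting phonation.
  An exemplar between two subject calls does not remove the
  subject-to-subject latency record; it only determines counter status.

## Response pairs and ratio metrics

A response pair compares the latency *into* a call with the latency *out*
of it. For an exemplar-to-subject (E-T) pair the triple
(subject call, exemplar, subject call) must be consecutive in the merged
call timeline: the first latency is the gap from the preceding subject
call's offset to the exemplar's onset (the operator's response time), the
second from the exemplar's offset to the answering subject call's onset
(the subject's response time). T-E pairs are the mirror construction. This
reading makes the two pair families overlap but not coincide, so their
counts differ, and it is the only reading that directly compares response
times. An alternative construction (successive same-source inter-call
intervals paired with the other source's following interval) is available
behind `strategy="same_source"` for sensitivity analysis but is not the
default.

The two latencies standardize to percentage shares of their total, making
the metric invariant to the absolute pace of the exchange. A pair is
*matched* when the minority share is at least 41% (the 41:59–50:50 band,
closed at both edges; a `1e-9` grace absorbs binary floating-point
round-off at the edge — e.g. 4.1 s vs 5.9 s standardizes to
40.999…% in floats). The *discrepancy* `100 − 2·share_small` is the
threshold-free companion metric; `matched ⇔ share ≥ 41 ⇔ discrepancy ≤ 18`
holds identically, and the test suite checks the equivalence, the swap
symmetry and the scale invariance over random pairs.

Phases with fewer than two pairs are flagged insufficient and excluded from
the matching contrasts, since a single pair cannot inform a proportion.

## Regression families

- **Latencies and discrepancies** are continuous but are analyzed with a
  count family; the minimal reconciliation is rounding to the nearest whole
  second (or percentage point), fitted by negative binomial (NB2)
  regression with log link. The dispersion α is estimated by maximum
  likelihood and the mean coefficients are then refitted by IRLS at that α
  — for the one-way categorical designs used here the coefficients do not
  depend on α (each level's fitted mean is its sample mean), so this is a
  numerical polish rather than a different estimator. When α collapses
  below 1e-4 or the NB likelihood fails, the model degrades to Poisson and
  the result is flagged. A Gamma/log fit on the raw latencies is available
  via `family="gamma"` as a sensitivity check.
- **Matching** is fitted by logistic regression of matched-vs-not on phase.
  Complete separation (a phase with 0% or 100% matched) makes the MLE
  diverge; affected contrasts are computed from the 2×2 table against the
  reference with the Haldane–Anscombe 0.5 correction and Woolf standard
  error, and flagged.
- **Amplitude** is fitted by ordinary least squares on either time in
  minutes (`TIME_MIN`) or the ordinal phase index 0/1/2 (`PHASE`), giving a
  decline in dB per minute or dB per phase step.
- Predictor levels with fewer than two observations cannot support a
  contrast; they are excluded from the design and flagged inestimable.

Useful exact identities follow from the one-way structure and anchor the
tests: the two-group count-family coefficient equals the log ratio of group
means for any dispersion, and the two-group logistic coefficient equals the
2×2 log odds ratio.

## Randomization tests

Because a single encounter gives a small sample, each contrast can be
checked by permutation: the predictor labels are shuffled uniformly without
replacement (seeded), the coefficient recomputed, and the two-sided
empirical p-value estimated as `(1 + #{|β*| ≥ |β_obs|}) / (N_valid + 1)` —
the add-one estimator avoids p = 0 and is standard resampling practice.
Permutations for which the coefficient is undefined (a permuted group with
zero mean under a log link, or separation under the logit) are excluded
from the denominator; the procedure aborts if more than 10% fail.

For the one-way categorical fits used throughout, the permuted coefficient
is evaluated in closed form (log group-mean ratio, log odds ratio, or mean
difference) — exactly the MLE a refit would return, at a fraction of the
cost. The observed labelling is evaluated by the same route so that ties
are exact: with a constant outcome every β* equals β_obs equals 0 and the
p-value is exactly 1. Fixed seeds make the whole null distribution
bit-reproducible.

## The synthetic session generator

No recordings ship with the package, so validation rests on a generator
that reproduces the structure the analysis assumes. One playback session is
an alternating timeline over a 20-minute window (default): the operator
broadcasts three initial exemplars, then each broadcast is answered with
the current phase's response probability. An answer latency is either
*coupled* — with the phase's coupling probability π the subject reproduces
the operator's preceding latency up to multiplicative Gaussian noise (the
coupled-oscillator behavior the matching analysis is designed to detect) —
or drawn fresh from the phase's Gamma distribution (positive, right-skewed,
mean and shape interpretable). The operator either mirrors the subject's
last latency plus Gaussian noise (`MIRROR_SUBJECT`, the adaptive-playback
default) or broadcasts at a fixed mean (`FIXED_MEAN`).

Defaults describe the emulated study conditions: phases at 0–420–900–1200 s
(engagement/agitation/disengagement); response probabilities
0.95/0.85/0.5; Gamma response-latency means 8/14/25 s with shape 4;
coupling probabilities 0.8/0.3/0.1 with 5% coupling noise; seven scheduled
blows (two neutral early, three wheezy mid-session, two neutral late);
broadcasts cease at 960 s, after which the subject produces three trailing
calls in succession at spontaneous latencies before falling silent;
amplitudes −25 dB base with phase effects 0/−6/−12 dB and 2 dB noise. With
these settings a session yields ≈38 broadcast exemplars and ≈34 subject
calls — the scale of a real single-subject 20-minute exchange.

Three structural choices deserve explanation:

- **Blows delay the answer they interrupt** (`blow_delay_s`, default 15 s)
  in addition to suppressing its counter-call status: surfacing to breathe
  interrupts phonation, and in real exchanges the latencies following a
  blow are the visibly longest in the series. Without this, "non-counter"
  calls would be statistically identical to counter calls and the
  counter-call contrast would have no ground truth to recover.
- **The succession tail** (`n_trailing_calls`, default 3) models the
  winding-down of an exchange: unprompted calls at the spontaneous
  (control-day) latency scale. These are the archetypal non-counter calls.
- **Spontaneous calling is slow** (`control_latency_mean_s`, default 60 s,
  normal with 10 s SD truncated at zero): subject-to-subject latencies
  during playback run near *twice* the response latency (operator gap plus
  answer), so for the control day to sit above every playback phase — the
  qualitative day contrast the analysis tests — its mean must exceed
  ≈2×25 s.

The generator records every draw in a `GroundTruth` object: per-response
phase, the phase whose parameters generated the draw (the onset may spill
into the next phase), the coupling indicator, the pre-delay base latency,
blow suppression, amplitudes, operator latencies and the unanswered
exemplars. Recovery tests compare analysis output against these records.
Two subtleties matter when validating the generator against its own
parameters: draws must be compared under the *generating* phase (onset
phase mislabels boundary draws), and blow-suppressed draws must be compared
on their pre-delay base latency (a blow lands in longer windows more often,
so excluding suppressed draws selects against long ones).

### Scenario presets

- `paper_like` — the defaults above: shortest and most strongly coupled
  latencies during engagement, intermediate agitation, long disengagement
  with amplitude decline.
- `null` — all phases share one parameter set, zero coupling, no blows, no
  tail, and a fixed-mean operator equal to the response mean. The last
  three choices are what make the null *true* for permutation tests: a
  mirroring operator autocorrelates successive latencies while phase labels
  are contiguous time blocks, so row exchangeability would fail even with
  identical phase parameters; likewise a phase-structured blow schedule or
  an operator warm-up transient each induce real label effects.
- `perfect_oscillator` — deterministic mimicry (π = 1, all noise zero,
  fixed-mean operator): every response pair standardizes to exactly 50:50.

## What the tests do and do not show

The suite verifies, on 200 seeded replicate sessions per experiment:
uncoupled latency draws match their Gamma means within two standard errors;
the engagement-phase match proportion exceeds agitation's in ≥95% of
replicates; the mean fitted amplitude decline is within 1 dB of the
generator's −6 dB/phase; the counter-call contrast's sign is recovered in
≥95% of replicates; and under the `null` preset the randomization p-value
is uniform (Kolmogorov–Smirnov at α = 0.01) and bit-reproducible under a
fixed seed. Problem sizes (200 replicates, 1,000 permutations, ~35 calls
per session) were chosen to estimate these proportions to a few percent
while keeping the default suite fast.

These are *internal-consistency* results: they show the pipeline measures
what the generator put in, at single-session sample sizes. They do not show
that real exchanges satisfy the generator's assumptions — independent Gamma
latencies, memoryless coupling to only the immediately preceding operator
latency, deterministic blow schedules, stepwise amplitude phases. Real
data add measurement error in onset/offset annotation, drifting
propagation conditions affecting amplitude, and possible longer-range
temporal dependence, none of which are modeled. With one subject and one
encounter, the GLMs here (deliberately, matching the single-event design)
have no random-effect structure and cannot generalize beyond the analyzed
individual; the randomization test addresses spuriousness within the
event, not population-level inference.

## Numerical notes

- Latency arithmetic is plain float64; selection-table round-trips preserve
  times to well under 1 ms.
- The matched-band edge uses a `1e-9` grace (see above); shares are clamped
  so an exactly equal pair standardizes to 50.0, not 50 + ε.
- NB dispersion is estimated by BFGS on the NB2 likelihood with a Poisson
  fallback at α < 1e-4 or on failure.
- All randomness (generator and permutations) flows through
  `numpy.random.default_rng` seeded from the user-supplied seed; reports
  record the seed used.
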