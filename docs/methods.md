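# Methods

`tinnpsych` implements a complete in-silico psychoacoustic measurement
pipeline for studying pure-tone detection near the tinnitus pitch-matched
frequency (f_tp): adaptive staircases for pitch matching and hearing
thresholds, a constant-stimuli run design, Bayesian psychometric-function
fitting with highest-density-interval (HDI) comparisons, control matching,
virtual observers, and a Monte-Carlo study of threshold-shift detectability.
This note records the model, its assumptions, the tunable parameters, and the
design choices made where the design was genuinely open.

## Detection model

Detection of a tone at level `x` (dB SPL) follows the Gumbel (log-Weibull)
psychometric function

    psi(x) = gamma + (1 - gamma - lambda) * (1 - exp(-10^(beta (x - alpha))))

with threshold `alpha` (dB SPL; the level detected with probability
`gamma + (1-gamma-lambda)(1-1/e)`), slope parameter `beta` (per dB inside the
log10 exponent), false-alarm rate `gamma` (lower asymptote), and lapse rate
`lambda` (`1 - lambda` is the upper asymptote). The maximum rate of rise is
`beta' = (1-gamma-lambda) * beta * ln(10)/e` (psi per dB); we report `beta`
rather than `beta'` to avoid spurious correlation with the asymptote
parameters. Silence (catch) trials are encoded as a level of negative
infinity and contribute to the likelihood only through `gamma`.

## Bayesian fitting

The posterior is evaluated on a dense `(alpha, beta)` grid — `alpha` from 0
to 90 dB in 0.25-dB steps by default, `beta` on 120 log-spaced points in
(0.01, 1] — with `gamma` and `lambda` profiled at their penalized-likelihood
optima per grid cell, followed by Nelder-Mead (Simplex) refinement of the MAP.
Priors: `alpha ~ Normal(45 dB, 30 dB)`; `beta ~ Beta(0.1, 1)` read as a
density on `beta` over (0, 1]; `gamma` and `lambda` uniform on [0, 0.25] and
[0, 0.10] (weakly informative ranges spanning observed values). Design
choices worth flagging:

* **Nuisance profiling resolution.** `gamma` and `lambda` are profiled on
  11 x 5 uniform grid points. With 20 silence trials and 10 trials at the
  "free-trial" top level per run, the data resolve these rates to about 0.05
  anyway; the Simplex refinement recovers continuous MAP values. The top
  level (4–6 dB above the second highest) is retained in the likelihood so
  that errors there inform `lambda`, rather than being discarded.
* **Marginals and HDIs.** Marginal posteriors are grid masses (beta cells
  carry their log-spacing widths). The HDI of a discretized marginal is the
  smallest set of cells reaching the target mass; density ties are broken
  toward the center of mass (a uniform density yields the central interval),
  and disjoint (multimodal) HDIs are returned as a flagged union, never
  silently merged.
* **Degenerate data.** A run whose responses are all-yes or all-no raises a
  degenerate-fit error carrying a diagnostic; an empty run returns the prior.
  A MAP on the edge of the `alpha` grid sets a boundary flag.
* **Threshold-difference test.** The posterior of `alpha_B - alpha_A` is
  built from 10,000 independent draws per run from the two discretized
  `alpha` marginals (with uniform within-cell jitter of half a grid step to
  smooth the discretization); the difference is significant when 0 falls
  outside its 95% HDI (computed with `arviz.hdi`). Two runs at the same
  frequency are pooled (trials concatenated) when not significantly
  different; otherwise the run with the smaller `alpha` posterior SD — the
  only available precision metric — is selected.
* The slope-difference test between the two test frequencies averages
  per-participant slope-difference draws across the cohort and reports the
  95% HDI of the group-mean difference.

## Measurement protocol

* **Loudness grid:** 18 tones, 0.8–16 kHz at 4 per octave. Presentation
  levels for pitch/octave/tonality tests are the loudness match + 10 dB,
  capped at 90 dB SPL. The hearing limit is the highest frequency audible at
  the 90 dB SPL cap.
* **Pitch staircase (2-AFC, recursive):** the pair starts at the initial
  estimate and 0.9 oct above; the chosen tone anchors the next pair on its
  own side. A choice change is a reversal; the separation shrinks per
  reversal by 0.5^0.5, 0.5^0.25, 0.5^0.125, 0.5^0.125 (one factor per
  reversal in four sets of four), reaching exactly 1/16 of the start after
  16 reversals, which is also the stopping rule (the schedule covers exactly
  16 reversals; the stopping rule is not separately stated in the protocol,
  so termination upon the 16th reversal is adopted). The estimate is the mean
  of the pair midpoints (octaves re 1 kHz) at the last four reversals. When a
  tone would cross the audible-range edge the pair is clamped to the edge and
  one extra separation reduction is applied without counting a reversal;
  repeated edge contacts keep the tones minimally distinct (1e-9 oct floor).
  Separation is re-anchored from the cumulative factor (equivalent, under
  this schedule, to reducing the current value).
* **Threshold staircase (yes/no, 1-up/1-down):** start 20 dB above the
  audiogram threshold when the audiogram covers a frequency within 0.5 oct,
  else 70 dB SPL; steps 8, 4, 2, 1 dB, decreasing after the first three
  reversals; stop after five further reversals at 1 dB; estimate = mean level
  at those last five reversals. Converges near the 50%-response level.
* **Constant-stimuli run:** 90 trials — seven levels at the rounded-down
  threshold estimate + {-8, -4, -2, 0, +2, +4, +8} dB, 10 trials each, plus
  20 silence trials — in ten randomized blocks of nine (each finite level
  once, silence twice, per block). Between the two runs all levels except the
  highest may shift ±2 dB toward a 50% overall detection rate; the trigger
  band is a design choice here: +2 dB below 0.40, −2 dB above 0.60.
* **Verification gates:** octave confusion (3 tones — f_tp and ±1 oct, or
  f_tp, −0.5 and −1 oct when +1 oct is inaudible — 3 pairs x 5 repeats;
  pass requires ≥60% f_tp choices in each pair containing f_tp, applied
  per pair with the aggregated fraction also reported); tonality (tone vs
  ½-oct noise, 1/6-oct noise, 3-oct noise, 3-oct noise + tone, 6 repeats
  each, ≥60% tone choices per comparison); pitch consistency (first
  successive pair of day-1 estimates within 0.4 oct over ≤5 runs, same on
  day 2 over ≤3 runs, day means within 0.4 oct; the day-2 estimate is the
  final f_tp).
* **Eligibility:** pure-tone average (0.5/1/2/4 kHz, better ear) ≤45 dB HL;
  age 18–70; for the tinnitus group, tonal/binaural/>6-month/maskable
  tinnitus, consistent pitch match, THI < 78; exclusions for interaural
  asymmetry (>10 dB at f_tp or 0.6 oct below, evaluated at the nearest
  audiogram frequency; >20 dB PTA), air-bone gaps (mean >10 dB or two
  consecutive frequencies >15 dB), loss >70 dB HL at the test frequencies,
  and hypersensitivity/hallucination/neurological/other-study flags.
* **Control matching:** per control, the five tinnitus participants nearest
  in 4–8 kHz mean hearing loss (both ears) are shortlisted; the nearest
  hearing limit decides, then nearest age, then stable id order. The control
  inherits the matched participant's f_tp. Matching is deterministic and
  order-independent.

## Virtual observers

The synthetic cohort stands in for raw data that were never deposited. Each
observer carries: a sloping audiogram (flat low-frequency base near 10 dB HL
rising so the 4–8 kHz mean matches the group target — tinnitus 36.1 ± 14.5,
control 27.6 ± 11.3 dB HL — rounded to 5-dB audiometric steps, monotone,
with small interaural jitter and near-zero air-bone gaps); a hearing limit
(truncated normal, tinnitus 11.5 ± 2.4 kHz, control 11.9 ± 1.9 kHz); Gumbel
detection parameters (slope 0.14 ± 0.04, false-alarm rate ~0.03, lapse rate
~0.005, truncated to positive ranges); and, for the tinnitus group, an
internal pitch placed below the hearing limit by a gap drawn from
N(0.43, 0.53) oct truncated at zero, a matching-noise SD of 0.15 oct (chosen
so that a realistic fraction of candidates fails the 0.4-oct consistency
gate; a tunable, not an empirical claim), a per-tone perceptual jitter of
0.02 oct (a frequency difference limen, so near-identical tones are
discriminated at chance), tinnitus loudness of 5–10 dB SL, and a THI score
~N(40, 20) clipped below 78. Demographics (age, sex fraction) follow the
group targets; sex is recorded but has no effect on responses.

The detection threshold at arbitrary frequency interpolates the binaural-mean
audiogram monotonically (PCHIP) in dB SPL — using an embedded ISO-389-style
reference-threshold offset table for circumaural audiometric headphones —
and above 8 kHz rises linearly in octaves to 90 dB SPL at the hearing limit,
beyond which tones are inaudible at the presentation cap. Detection responses
are Bernoulli draws from the observer's curve; 2-AFC pitch choices pick the
tone nearer the jittered internal pitch; loudness matches are threshold +
tinnitus sensation level (tinnitus group) or the just-audible threshold
(controls, modeled as the threshold), capped at 90 dB SPL. Tonality choices
use a fixed tone-preference probability (default 0.9). All responses are
seed-deterministic; cohort generation spawns one child stream per observer
from a single seed.

What the generator does **not** emulate: loudness recruitment, masking and
residual inhibition, response delays beyond an optional constant, cochlear
dead regions, octave confusions (observers are built pitch-veridical), level
effects on pitch, headphone placement variability, and within-day versus
between-day pitch variance as separate components (both are exposed through
the single matching-noise parameter). Within-pair order effects and
inter-stimulus timing are out of scope. Passing tests therefore demonstrate
correctness of the measurement and analysis machinery under the assumed
generative structure, not properties of real listeners.

## Shift-detectability simulation

Pairs of 90-trial runs are drawn from generating curves with midpoints 0 and
`shift` dB (shifts 0–3 dB; slopes 0.05–0.5 on the grid axis; generating
`gamma = 0.02`, `lambda = 0.005`, configurable — nuisance values typical of
measured cohorts), both runs sharing the same level set anchored at 0.
"Midpoint" maps to the Gumbel `alpha`, since that is the parameter the HDI
test compares. Each run is fitted, the threshold-difference test applied,
and the pooled data refitted; per cell the simulation reports the
significance rate, mean fitted shift, and pooled-fit slope bias.
"Becomes significant" is operationalized as a significance rate above 0.5
(majority of replicate pairs; the criterion is exposed as configuration).
For this simulation the fit uses the standard step, priors and profiling on
an `alpha` grid spanning −15 to 18 dB, re-centered so the 0-dB reference
midpoint is interior to the grid rather than on its edge.

At the steep end (slope 0.5) shifts become majority-significant at 1.5 dB.
At the shallow end (slope 0.05) the majority criterion is reached only near
6 dB: a single 90-trial run at that slope carries threshold information
worth a posterior SD of ~1.5 dB, so the difference posterior is ~2.1 dB wide
and a calibrated 95% HDI test cannot reject a 3-dB shift in most pairs — an
oracle test with all nuisance parameters fixed at truth reaches only ~39%
at 3 dB. The acceptance script therefore extends the shallow-slope shift
scan beyond 3 dB and reports the measured crossing. Zero-shift cells show
negligible bias in both the fitted shift and the pooled-fit slope.

## Problem sizes and numerical choices

Default study sizes follow the measured cohort (18 + 18 participants, two
frequencies — f_tp and 0.6 oct below, alternating test order — two runs per
frequency). The detectability simulation uses 200 replicate pairs per grid
cell and the precision study 72 pooled two-run datasets (thresholds drawn
from 35–55 dB SPL, slopes around 0.14, anchor fed by a staircase-like
estimate with 1 dB error); the precision study's fit grid spans 20–70 dB at
the standard 0.25-dB step. A batch fitter precomputes level-set-dependent
log-probability tables (float32) so that each additional fit reduces to two
tensor contractions; it is verified in the tests to agree with the single-run
path. Monte-Carlo suites in the tests use 100–1000 replicates as stated per
test. Staircase runners guard against non-termination with a 500-trial cap.

## Known limitations

* The profiled (rather than marginalized) nuisance treatment makes the
  `(alpha, beta)` posterior slightly narrower than a full 4-D
  marginalization; the measured type-I rate of the pooling test (~3.5% at
  slope 0.14) is nonetheless mildly conservative.
* HL→SPL conversion uses a single embedded offset table; transducer-specific
  calibration is out of scope.
* The slope prior's weight near zero noticeably shrinks single-run slope
  estimates at shallow true slopes; pooled fits at the study-typical slope
  are unbiased (bias < 0.3 dB on the threshold, slope recovered to
  ~0.005).
* Real-data ingestion is limited to the documented CSV/JSON trial formats;
  no audio is rendered or processed.
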