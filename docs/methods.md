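# Methods

This note documents the statistical model behind `tojlab`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Task and data model

One trial: two bilateral dynamic-plaid stimuli (radial or rotational
motion, initially same or opposite directions) reverse direction with a
signed asynchrony X ∈ {−200, −133, −67, 0, +67, +133, +200} ms (negative
= left lagging), and the observer reports which side changed first.
The analysis design is 2 × 2 × 7 × 20 = 560 trials per participant in
five 112-trial blocks following one practice block (block 0, retained in
files, excluded from every statistic). Frame-quantized asynchronies
(±66.67, ±133.33 ms at a 60 Hz refresh) are snapped to the nominal
values on ingest (tolerance ±1 ms); values farther off-grid are rejected,
since the nominal grid is an invariant of the design, not a measurement.
Reaction time is clocked from stimulus offset to keypress.

Zero-asynchrony trials carry no objectively correct answer; the
"correct" response on them is a pre-designated fair coin (used only for
feedback and response-bias/RT analyses). They never enter d′ or the
inclusion count.

## Signal detection

d′ = Z(hit proportion) − Z(false-alarm proportion) with Z(p) = 0.5 ·
Φ⁻¹(p): z-scores on a normal with SD 0.5, which makes d′ = 0.67 the
unbiased 75%-correct point and d′ ≈ 1.96 the ceiling of a 20-trial pool
after correction. A hit is a left-first response when the left side led
(X > 0); a false alarm is a left-first response when it lagged. Each
participant yields 16 values: 12 pairing the 20 trials at +X with the 20
at −X for each condition × |X|, and 4 pooling the 60 positive and 60
negative trials per condition. Extreme counts are corrected by half a
trial — 0 of n → 0.5/n, n of n → (n−0.5)/n — *only* at the exact
extremes; interior counts are untouched (no blanket log-linear
correction). Pools of any size other than 20/60 are rejected by default;
an `allow_any_n` override exists for simulation-scale convergence checks
(e.g. verifying that a guessing observer's d′ → 0 in 1000-trial cells)
and is not part of the canonical analysis.

## Psychometric functions and thresholds

For each group × condition, each participant contributes the proportion
of left-first responses per asynchrony (20 trials); the group ordinate is
the *median* across participants. A 2-parameter logistic
1/(1 + e^(−K(X−Xo))) is fitted by unweighted least squares on the 7
median points — unweighted because medians of proportions carry no
natural binomial weight, and no lapse parameter is fitted (the fitted
model has exactly slope and midpoint; lapses exist only in the
generator). Initialization: Xo₀ = the abscissa whose ordinate is nearest
0.5, K₀ from a logit-linear regression of the clipped ordinates; on
failure a bounded grid of slope restarts (10⁻⁴…0.1) is tried, and
persistent non-convergence raises an error carrying the points and the
per-start failures. Goodness of fit is the Pearson r between observed
and fitted ordinates (r and r² both reported).

The 75% threshold (JND) is half the asynchrony span that moves the
left-first rate from 0.25 to 0.75. For this logistic the span is
2·ln(3)/K, so the threshold is **ln(3)/K**; a brute-force check that
numerically locates the 0.25 and 0.75 crossings agrees to 1e-9 relative
tolerance. The threshold SE uses the delta method,
SE = ln(3)·SE(K)/K², with SE(K) from the least-squares covariance.

A caveat the tests respect: when a group's generating threshold exceeds
the ±200 ms stimulus range (possible in the hardest generator cell), the
7 ordinates span only part of the sigmoid and r² can fall below the
>0.97 regime typical of in-range conditions. The tight-fit property is
therefore asserted for conditions whose generating threshold lies inside
the tested range.

## Permutation inference

Both tests run 10,000 Monte Carlo simulations by default on **medians**,
because the Lilliefors screen (below) flags non-normal conditions.

*Pairwise group differences.* Statistic: median(d′ group A) − median(d′
group B). Each simulation permutes the pooled index vector (seeded
generator, argsort of uniforms) and re-splits into the original group
sizes. One-sided by default: p = #(null ≥ observed)/n_sims, significant
iff the observed value strictly exceeds the 95th percentile of the null.
A two-sided option and a +1/(n+1) p-value convention exist behind flags
but are off by default, matching the rank-within-the-simulated-
distribution description of the procedure. Exhaustive enumeration of all
group-size-preserving partitions serves as the oracle for small
instances; note that with heavily tied data a median statistic can be
reproduced by many partitions (e.g. {2,2,2} vs {0,0,0} has exact
p = 0.5), so "complete separation" does not imply a minimal p.

*2×2 interaction.* Statistic: (median RS − median RO) − (median RotS −
median RotO) over the per-participant cell values of one scope (one
group, or all participants). Each simulation independently permutes
every participant's four values across the four condition labels —
each participant's multiset, hence their overall level and the
consistent individual differences, is exactly preserved. The oracle is
full enumeration of the 24^n label assignments for n ≤ 3.

*Lilliefors screen.* KS distance between the sample ECDF and a normal
with mean and SD (ddof = 1) estimated from the sample; the p-value comes
from 10,000 seeded Monte Carlo replicates of standard-normal samples of
the same size rather than an analytic approximation — self-contained,
reproducible, and directly testable against an independent reference
implementation (statistics agree to 1e-12; p-values to Monte Carlo
error). Requires n ≥ 4 and a non-constant sample.

Determinism: every result is fully determined by (seed, n_sims); the
pipeline derives one sub-seed per test from the run's resampling seed.

## Reaction time and rank analyses

Median RT per participant per design cell (28 cells), group value =
median of participant medians. Group difference lists are the 28
cell-wise differences of group medians per ordered pair, summarized by
their median and by the smallest/largest difference *by magnitude*
(signs kept) — the form the difference tables take. The chance
probability of one fixed strict ordering of g groups recurring in all c
conditions is (1/g!)^c; for 3 groups and 28 conditions this is
1.63 × 10⁻²².

Rank analyses use average ranks for ties (the standard convention;
Pearson on ranks = Spearman). For the RT-vs-d′ coupling, ranks are
oriented so better performance gets the lower rank on both metrics
(RT ascending, d′ descending); participants of all groups are ranked
jointly within each condition, the d′ entering is the pooled-asynchrony
value (one per condition), and per-group trendline slopes accompany the
overall correlation. Within-group consistency matrices correlate each
pair of the four motion conditions on d′ ranks and RT ranks separately.

## Inclusion screening

Exact one-tailed binomial: p = P(X ≥ n_correct | n = 480, 0.5), included
iff p < 0.001 (strict). The package computes the minimal included count
from the exact tail — k\* = 275 of 480 = 57.29% — and reports it
alongside the conventional 57.5% (276/480) operational figure; the two
are deliberately not reconciled, and the screen itself uses the exact
test, not a percentage cut.

## Synthetic observers

Each observer responds left-first with probability λ/2 + (1−λ)·
logistic(K_cell(X − Xo_cell)). The lapse λ enters symmetrically
(floor λ/2, ceiling 1−λ/2) so the generative midpoint stays at Xo and
parameter recovery is well-posed. Reaction times are shifted lognormal —
rt = b/2 + (b/2)·exp(σZ) with median b — giving positive support and
right skew, plus a deterministic penalty at X = 0 that reproduces the
central-tendency slowing when the stimulus carries no order information.
No published RT model exists for this task; shifted lognormal is a
conventional choice.

Cohort-level defaults are the study conditions and are not tuning knobs:

| parameter | default | rationale |
|---|---|---|
| group sizes | 25 / 67 / 29 (+0 / 4 / 7 guessers) | included and screened-out counts of the three expertise groups |
| median thresholds | 40 / 80 / 160 ms | order-of-magnitude span of the published group medians |
| interaction profile | ×1.0 RS, ×2.0 RO, ×1.0 RotS, ×0.8 RotO | radial-opposite roughly doubles thresholds; rotational-opposite is relatively easy |
| threshold dispersion | lognormal σ = 0.3 observer-level (+σ/2 per-cell jitter) | realistic inter-observer spread; the shared observer factor produces the positive within-group cross-condition rank correlations seen in real cohorts |
| bias Xo | N(0, 8 ms) | midpoints cluster near 0 (non-biased responding) |
| lapse | U(0, 0.04) | a few percent of attention/motor errors |
| RT medians | 600 / 674 / 740 ms | reproduces ≈ −74 and −66 ms pairwise group median differences |
| zero-asynchrony RT penalty | 150 ms | visible slowing at X = 0 |
| RT noise | lognormal σ = 0.25 | typical RT skew |

Guessers are implemented as observers with a flat response curve
(threshold 10⁹ ms) rather than λ = 1, keeping the lapse invariant
0 ≤ λ ≤ 0.1 intact; they fail the binomial screen with probability
≈ 1 − 10⁻³.

What the generator does *not* emulate: sequential effects and learning
within a session, block structure beyond bookkeeping, response-bias
drift, RT–sensitivity coupling at the individual level (faster observers
are not made more sensitive within a group — the observed RT×d′ rank
correlation in synthetic cohorts arises from between-group structure
only), and any perceptual mechanism (attention capture by looming,
motion integration). Passing tests therefore validate the statistical
machinery on data with the assumed structure; they do not certify the
perceptual claims of any particular dataset.

## Tempo and angle conversions

Note duration = 60000/tempo/subdivision ms; temporal frequency =
tempo·subdivision/60 Hz (reciprocity exact before rounding); threshold
frequency = 1000/threshold. Angular mismatch = asynchrony × rotation
rate, default 0.72°/ms (360° per 500 ms); antiphase (180°) at 250 ms.
All functions return unrounded values — rounding to the printed
precision happens in the reporting layer, because the conventional
tables mix 2-decimal and integer cells. Note that 133 ms × 0.72°/ms =
95.76°, which rounds to 96°; the conventionally quoted 95° for this
asynchrony is not reproducible from the stated rate and the package
reports the unrounded value.

## Problem sizes used by the test suite

Simulated checks run at the sizes the properties require, chosen once:
study-sized cohorts (121–132 participants × 560 trials) for bookkeeping,
inclusion, and threshold recovery (50 seeds, median criterion);
10,000-simulation permutation tests against exhaustive enumeration for
≤ 10 participants; 2,000-replicate calibration runs with 1,000
simulations per test; 10,000-draw convergence checks of the response
model. The full suite completes in about a minute on one core.
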