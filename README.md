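# tojlab

Analysis pipeline for two-alternative visual **temporal-order-judgment
(TOJ)** psychophysics. It is written for researchers who run (or
re-analyze) experiments in which an observer watches two bilateral motion
stimuli that change direction with a signed asynchrony *X* and reports
which side changed first, and who want the complete statistical treatment
of such data as tested, reusable code:

- **signal-detection sensitivity** — d′ = *Z*(hits) − *Z*(false alarms)
  with the *z*-distribution SD set to 0.5 (so d′ = 0.67 is unbiased 75%
  correct), hits/false alarms being left-first responses when the left
  side led/lagged, with half-trial corrections at extreme counts
  (0 → 0.5/*n*, *n* → (*n* − 0.5)/*n* for pools of 20 or 60);
- **psychometric thresholds** — unweighted least-squares fits of
  *p*(left first | X) = 1/(1 + e^(−K(X−Xo))) to group median response
  proportions, with the 75% just-noticeable difference ln(3)/K and its
  delta-method standard error;
- **median-based Monte Carlo permutation inference** — pairwise group
  differences of median d′ (re-partitioning pooled values into the
  original group sizes) and the 2×2 motion-type × initial-directions
  interaction (Radial Same − Radial Opposite) − (Rotational Same −
  Rotational Opposite), shuffled *within* participants so consistent
  individual differences are preserved exactly; plus a Monte-Carlo
  Lilliefors normality screen that motivates the median-based approach;
- **reaction-time analyses** — participant/group median RTs in all 28
  design cells, group difference lists, the chance probability
  (1/g!)^c of a fixed group ordering recurring in every condition, and
  Spearman-equivalent rank correlations (RT vs d′, and within-group
  consistency matrices across stimulus conditions);
- **inclusion screening** — exact one-tailed binomial test against chance
  over the 480 nonzero-asynchrony trials at p < 0.001;
- **tempo utilities** — conversions between TOJ thresholds, musical
  subdivisions (60000/tempo/subdivision ms), temporal frequencies, and
  color-guard rifle rotation angles (0.72°/ms by default);
- **a synthetic-observer generator** that emulates the study design
  (3 expertise groups, 2 motion types × 2 initial directions × 7
  asynchronies from −200 to +200 ms × 20 repeats = 560 analysis trials
  per participant) with per-cell logistic observers, symmetric lapse
  rates, and shifted-lognormal reaction times — so every downstream stage
  is testable without any data download.

## Worked example

Simulate a study-sized cohort, screen it, and estimate group thresholds:

```bash
$ tojlab simulate --out trials.csv --seed 7
wrote 67760 trials (121 participants) to trials.csv

$ tojlab screen --in trials.csv --out inclusion.csv
percussion: 25/25 included (100.0%)
brass: 67/67 included (100.0%)
color_guard: 29/29 included (100.0%)

$ tojlab psychometric --in trials.csv --out fits.csv
percussion radial-same: threshold 42.0 ms (r2=0.9959)
percussion radial-opposite: threshold 78.8 ms (r2=0.9975)
percussion rotational-same: threshold 34.8 ms (r2=0.9979)
percussion rotational-opposite: threshold 33.0 ms (r2=0.9998)
brass radial-same: threshold 89.3 ms (r2=0.9981)
brass radial-opposite: threshold 171.2 ms (r2=0.9876)
brass rotational-same: threshold 82.7 ms (r2=0.9992)
brass rotational-opposite: threshold 65.9 ms (r2=0.9987)
color_guard radial-same: threshold 160.7 ms (r2=0.9916)
color_guard radial-opposite: threshold 249.3 ms (r2=0.9832)
color_guard rotational-same: threshold 138.5 ms (r2=0.9930)
color_guard rotational-opposite: threshold 125.4 ms (r2=0.9956)
```

Each threshold is the asynchrony change (in ms) halving the span between
25% and 75% left-first responding: smaller = finer visual timing. The
output reproduces the generator's built-in structure — percussion finest,
brass intermediate, color guard coarsest; radial-opposite hardest and
rotational-opposite relatively easy — and every fit explains >97% of the
ordinate variance. `tojlab dprime`, `tojlab mc`, `tojlab rt`, and
`tojlab run` (full pipeline with a JSON manifest; identical configs give
byte-identical outputs) cover the remaining stages; `tojlab tempo --bpm
180 --subdivision 8` prints the musical-subdivision grid.

The same operations are available as a library:

```python
from tojlab import CohortSpec, simulate_cohort, apply_screen, dprime_frame, fit_all

trials = simulate_cohort(CohortSpec(seed=7))
included, report = apply_screen(trials)
thresholds = fit_all(included)          # 12 rows: group x condition
```

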