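# stepgoals

Analysis pipeline for intra-day step-tracker data from incentive
programmes with daily step goals (5000 / 7500 / 10,000 steps). The
package cleans raw 30-minute step blocks, fits hour-specific Bayesian
two-part (hurdle) models conditioned on accumulated steps and
demographics, forward-simulates end-of-day totals, and derives the
smallest 500-step accumulated thresholds that put a participant on track
for each daily goal.

Because the original programme data are restricted, the package ships a
first-class synthetic generator (`stepgoals.synthetic`) that reproduces
the statistical structure the analysis assumes — diurnal weekday/weekend
activity profiles, a high proportion of zero hours, right-skewed positive
counts, demographic effects, and a behavioural bunching spike just above
the 10,000-step goal. The generator draws from exactly the same two-part
model cells the inference module fits, so generating parameters are
recoverable (the basis of the parameter-recovery acceptance suite). The
generative process is this artifact's own construction and is not taken
from any external data source.

## Modules

| module | purpose |
| --- | --- |
| `stepgoals.synthetic` | profiles, hourly counts, 30-min block records with known ground truth |
| `stepgoals.preprocess` | block cleaning, hourly aggregation, demographic filters, study window |
| `stepgoals.descriptives` | reward-point arithmetic, daily/hourly summaries, cluster-robust joint F test |
| `stepgoals.twopart` | logistic + gamma(log link) hurdle likelihood per hour x day type x stratum |
| `stepgoals.inference` | adaptive random-walk Metropolis, Gelman–Rubin ratio, posterior summaries |
| `stepgoals.forecast` | forward simulation, goal probabilities, threshold recommendations |
| `stepgoals.pipeline` | orchestration, configuration, parameter-recovery experiment |

## CLI

```bash
stepgoals all --config config.yaml --outdir runs/demo   # full pipeline
stepgoals generate --outdir runs/demo                   # or stage by stage
stepgoals preprocess --outdir runs/demo
stepgoals describe  --outdir runs/demo
stepgoals fit       --outdir runs/demo
stepgoals recommend --outdir runs/demo
stepgoals forecast  --outdir runs/demo --hour 18 --cum 6000 --day-type weekday --goal 10000
stepgoals recover   --n-rows 5000
```

Example `config.yaml` (all fields optional; defaults are desk-scale and
finish in well under a minute):

```yaml
seed: 1
fit_hours: [18, 19, 20, 21, 22, 23]
recommend_hours: [18, 19, 20, 21, 22, 23]
generator:
  n_participants: 50
  date_start: '2018-01-08'
  date_end: '2018-01-21'
mcmc:
  n_chains: 4
  n_burn: 300
  n_keep: 300
```

Scaling `n_participants`, the date window and the MCMC sizes up to the
study-scale configuration (thousands of participants, 5000 burn-in and
5000 kept draws over 4 chains) is purely a matter of configuration.

Pipeline outputs land in the run directory: `participant_days.csv`
(24 hourly columns per participant-day), `exclusions.json`,
summary CSVs, per-cell posterior draws under `draws/`, an `rhat.csv`
convergence table (cells with Rhat >= 1.01 flagged), a
`recommendations.csv` threshold grid, and `manifest.json`.

## Notes on conventions

- Evening strata: accumulated-count intervals [0, 5000), [5000, 7500),
  [7500, 10000), [10000, inf), applied for hours 12–23; hours 0–11 use a
  single morning specification without the cumulative covariate.
- Group boundaries (age, BMI) are half-open and lower-inclusive.
- The gamma part treats positive counts as continuous; generated data are
  rounded draws (floored at 1), a documented approximation.
- The Gelman–Rubin ratio is the pooled (concatenated, ddof=1) standard
  deviation over the mean per-chain standard deviation — no split-chain
  or rank-normalisation refinement.
- Recommendation thresholds use a mean-crossing rule by default (smallest
  grid value whose predicted mean end-of-day total reaches the goal); a
  probability-based criterion is available via `criterion: probability`.
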