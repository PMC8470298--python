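# dolphinwatch

Quantifying how vessel traffic disturbs the behaviour of wild dolphin
groups, from focal-follow scan-sampling data.

Marine-mammal field teams record the predominant behavioural state of a
tracked dolphin group at fixed 3-minute intervals, together with the number
of dolphin-watching vessels nearby, the vessels' compliance with the local
code of conduct, and the group's response to approaches. `dolphinwatch`
turns such scan tables into the two standard disturbance analyses:

1. **Markov chain comparison.** The behavioural sequence over the five
   observed states (resting, travelling, socialising, diving, milling) is
   modelled as a first-order time-discrete Markov chain, fitted separately
   for *control* pairs (no vessels at either scan) and *impact* pairs
   (vessels at both scans); mixed pairs are *transition* conditions and
   enter neither chain. From the condition-specific contingency tables the
   package estimates

   - transition probabilities `p_ij = a_ij / Σ_j a_ij`,
   - behavioural budgets (share of time per state),
   - mean bout lengths `t_ii = 1 / (1 − p_ii)` transition units, with
     `SE = sqrt(p_ii (1 − p_ii) / n_i)`,
   - stationary distributions `π` solving `πP = π`, and
   - expected recovery times `E(T_j) = 1 / π_j`,

   and compares conditions with Pearson chi-square tests (row-wise chain
   homogeneity, per-cell 2×2 tests, budget proportion tests; no continuity
   correction) and Student's t-tests on bout lengths.

2. **Avoidance mixed models.** Whether a group avoids approaching vessels
   (vs neutral or attraction responses) is a Bernoulli outcome with a logit
   link, fixed effects from {behaviour, vessels, compliance, cohesion,
   group size} and a random intercept per focal group. The marginal
   likelihood is maximised under a Laplace approximation; all 32 additive
   candidate models are ranked by
   `AICc = −2 logLik + 2k + 2k(k+1)/(n−k−1)` and summarised with Akaike
   weights `w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)`. Fits are checked with
   simulation-based scaled residuals and population-level prediction curves
   with Wald bands.

A synthetic focal-follow generator (`dolphinwatch.synth`) reproduces the
statistical structure of such a study — short follows, a persistent
vessel-presence process, regime-switching behavioural chains, covariates and
avoidance responses — with exact ground-truth bookkeeping, so the whole
pipeline is testable without field data.

## Worked example

```python
import numpy as np
from dolphinwatch import bout_length, recovery_times, akaike_weights

for p in (0.04, 0.58, 0.95):
    est = bout_length(p, n_i=30)
    print(f"p_ii = {p:.2f} -> {est.mean_minutes:6.2f} min "
          f"(reported {est.reported_minutes} min)")

for pi_j in (0.33, 0.42):
    pi = np.array([pi_j] + [(1 - pi_j) / 4] * 4)
    print(f"pi_j = {pi_j:.2f} -> {recovery_times(pi).reported_minutes[0]} min")

deltas = [0.00, 3.75, 4.99, 6.33, 7.85, 9.34, 11.45, 12.28, 12.57,
          15.28, 15.94, 16.59, 16.68, 21.13, 21.31]
print(f"best-model weight: {100 * akaike_weights(deltas)[0]:.0f}%")
```

prints

```
p_ii = 0.04 ->   3.12 min (reported 3 min)
p_ii = 0.58 ->   7.14 min (reported 7 min)
p_ii = 0.95 ->  60.00 min (reported 60 min)
pi_j = 0.33 -> 9 min
pi_j = 0.42 -> 7 min
best-model weight: 76%
```

A self-transition probability of 0.95 at 3-minute scans therefore means an
expected one-hour bout — the scale of the shift seen in milling when
vessels are present — while a steady-state share of 0.33 means the group
returns to that state every ~9 minutes. A 3.75-point AICc gap already
concentrates three quarters of the evidence on the best candidate model.

The scripts in `examples/` walk through each capability end to end
(simulation, chain comparison, model selection, formulas); run them from
any directory, e.g. `python examples/02_markov_comparison.py`.

## Command line

```sh
dolphinwatch run --outdir out --seed 7            # full pipeline on synthetic data
dolphinwatch run --input scans.csv --outdir out   # ... or on your own scan table
dolphinwatch simulate --outdir sim --seed 7       # just write a synthetic dataset
dolphinwatch transitions --input scans.csv --output tr.csv
```

`run` writes per-condition transition matrices, the budget/bout/recovery
tables, all test statistics, the model-selection table, coefficient and
prediction CSVs, and a single `summary.json` from which every CSV is
derived. The input schema is one row per scan:
`follow_id, scan_index, state, n_vessels, compliant, group_size, cohesion,
response` (optional fields may be empty).

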