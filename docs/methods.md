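# Methods

## Data model

The unit of observation is the *scan*: every 3 minutes the predominant
behavioural state of ≥50% of a tracked dolphin group is recorded, together
with the number of dolphin-watching vessels within 300 m, vessel compliance
with the local code (only defined when vessels are present), group size,
group cohesion (low / intermediate / high) and, when vessels are present,
the group's response (avoidance / neutral / attraction). A *focal follow*
is one ordered scan sequence for one group on one day; the protocol spans 2
to 15 scans, and lengths outside that range are warnings rather than
errors, since real data deviate.

The ethogram has six mutually exclusive states. Feeding is accepted on
input but flagged and excluded from the analysis by default, which operates
on the five states actually observed in this kind of coastal daytime study
(resting, travelling, socialising, diving, milling) in the fixed matrix
order REST, TRAV, SOC, DIV, MIL. The research platform itself is never
counted in `n_vessels`.

### Condition labelling

Each consecutive scan pair yields one behavioural transition, labelled from
its two endpoint vessel counts: *control* (0 vessels at both scans),
*impact* (≥1 at both), *transition* (presence changed). Transition pairs
are excluded from both chains. This pairwise operationalisation is the only
one observable from scan-level counts; a vessel that arrives and leaves
strictly inside a 3-minute interval is invisible to the data model. The
reported control share is control / (control + impact), i.e. the share
among analysable pairs.

## Markov chain analysis

Each condition's transitions form a 5×5 contingency table `a_ij`;
probabilities are row-normalised, `p_ij = a_ij / n_i`. Rows never observed
as a preceding state are flagged undefined rather than treated as errors.

**Chain comparison.** The global test is a row-wise homogeneity test: for
each preceding state the 2×K table (condition × succeeding state) is tested
with Pearson's chi-square after dropping succeeding states with zero
combined count; statistics and degrees of freedom are summed over rows, so
df = Σ rows (K_used − 1) and empty cells reduce df instead of contributing
fabricated zeros. Rows empty in both conditions are excluded with a
warning; rows observed in only one condition, and expected cell counts
below 1, flag the result as unreliable without blocking it. Individual
transitions are compared with 2×2 tests ("to j" vs "elsewhere" among
transitions out of i). No Yates continuity correction is applied anywhere —
the per-cell statistics of interest are of the uncorrected magnitude — and
no multiple-testing correction is applied, matching standard practice in
this literature. P-values come from the upper tail of the chi-square
distribution.

**Budgets.** The default behavioural budget is the distribution of
*succeeding* states among a condition's transition samples, which keeps the
budget sample size identical to the chain's transition count; a scan-based
alternative (`budget_source="scans"`, classifying each scan by its own
vessel presence) is available. Budgets are compared globally (chi-square on
the 2×5 count table, df = 4) and per state (two-sample proportion test =
uncorrected 2×2 chi-square, df = 1).

**Bouts.** The expected bout length is `t_ii = 1/(1 − p_ii)` transition
units. The standard error of `p_ii` is binomial, `sqrt(p_ii(1 − p_ii)/n_i)`,
and is propagated to the minute scale with the delta method,
`SE(t) = unit · SE(p)/(1 − p)²`. `p_ii = 1` yields a flagged infinite bout.
Bout lengths are compared with a two-sample t statistic on the minute scale
(difference of means over the combined SE) with pooled df
`n_i,control + n_i,impact − 2`; Welch–Satterthwaite df is available via
`welch=True`. Minutes are reported rounded to the nearest whole minute
(ties to even); unrounded values are always retained.

**Stationary distribution and recovery.** `π` solves `πP = π` (left
eigenvector for eigenvalue 1, verified to ‖πP − π‖ < 1e−10). The chain must
be irreducible on states with defined rows; reducible chains raise an error
naming the states outside the largest communicating class. Recovery times
are `E(T_j) = unit/π_j`. The source of `π` is configurable: the default
("budget") uses the observed budget proportions, whose reported recovery
times reconcile directly with the reported budgets (3/0.33 ≈ 9 min); the
alternative ("stationary") uses the fitted chain's eigenvector. The two
coincide for long single-regime sequences.

## Avoidance mixed models

Avoidance (vs neutral-or-attraction) is Bernoulli with a logit link. Fixed
effects are additive subsets of {behaviour (4 df), vessels (1), compliance
(1), cohesion (2), size (1)}; interactions are not considered. Reference
levels are non-compliant, high cohesion and resting, so coefficients read
as effects of compliance, looser cohesion and non-resting states; group
size enters untransformed. Every model carries a fixed intercept and a
random intercept per focal group (groups are resampled across days), giving
k = 1 + Σ term dfs + 1.

The marginal likelihood integrates the scalar random intercepts out with a
Laplace approximation at each group's posterior mode (inner Newton solve,
tolerance 1e−10), and is maximised over (β, log σ) with L-BFGS-B from a
deterministic start: the ordinary-logistic solution with σ = 0.1. log σ is
bounded in [log 1e−6, log 50]; an estimate at the lower boundary is flagged
and the model then coincides with ordinary logistic regression (verified in
the tests to 1e−4 in log-likelihood). Standard errors come from a
central-difference Hessian of the negative marginal log-likelihood; at a
boundary fit the σ row is profiled out. The implementation agrees with
lme4's `glmer` (Laplace, nAGQ = 1) to ~1e−2 on coefficients, σ and
log-likelihood on matched data, which the test suite checks through
`Rscript`.

AICc uses n = number of response observations, not number of groups.
Candidates that fail to converge are excluded from the selection table with
a warning; AICc ties break by smaller k, then description, for
determinism. During selection only log-likelihoods are needed, so standard
errors are computed lazily for the winning model.

Predictions are population-level (random intercept at 0) — whether to
marginalise over random effects instead is genuinely open for this kind of
figure; setting them to zero is the common choice and is stated here.
Unspecified categorical covariates sit at their reference, numeric ones at
the training mean; profiles outside the observed range warn as
extrapolation. The 95% band is Wald on the link scale, transformed through
the inverse logit.

**Residual diagnostics.** n_sim response vectors (default 1000) are
simulated from the fitted model with random intercepts redrawn; each
observation becomes a randomised quantile within its simulated
distribution, `r = (#less + U(#equal + 1))/(n_sim + 1)`, uniform on [0, 1]
under a correct model, summarised by a KS test. Note a structural
limitation established empirically during development: the *pooled*
uniformity test has essentially no power against an omitted covariate,
because the randomised PIT of a Bernoulli response is marginally uniform
whenever average rates are matched. Misspecification of the mean structure
is only visible conditional on the covariate, so the module also provides
`residual_predictor_test` (two-sample KS across the covariate's median
split), which does detect a strong omitted effect in the majority of
replicates.

## Synthetic generator

The generator emulates: 24 focal follows (configurable) of 2–15 scans;
vessel presence as a two-state persistence process (stay-present 0.94,
stay-absent 0.78, initial presence 0.78), giving roughly an 80/20
impact/control mix of analysable pairs; vessel counts, given presence, as
1 + NegBin(r = 2, p = 8/15) truncated at 12 — mean ≈ 2.75, SD ≈ 1.8, chosen
to match the reported scale of 2.4 ± 1.8 vessels (no published count
distribution exists; this calibration is a documented choice); compliance
as a logistic function of vessel count (intercept 2.6, slope −0.25,
≈ 87% compliant overall); group size Normal(50.87, 14.63) truncated at 2
and constant within a follow; cohesion i.i.d. per scan with probabilities
(0.3, 0.4, 0.3) — a simplification, real cohesion is serially correlated;
and avoidance from a logistic model (intercept −2.0, vessels +0.5,
compliance −1.5, size +0.02, cohesion low +0.2 / intermediate +0.5 vs high,
behaviour 0, random-intercept SD 0.8), calibrated so a typical compliant
encounter crosses 50% avoidance around four vessels. Responses exist only
when vessels are present.

Regime matrices default to `P = a·I + (1 − a)·1qᵀ`, whose stationary
distribution is exactly `q`: control uses a = 0.55 with
q = (0.42, 0.08, 0.33, 0.10, 0.07) and impact a = 0.75 with
q = (0.27, 0.23, 0.10, 0.08, 0.32), reproducing the qualitative disturbance
signature (less resting/socialising, more travelling/milling, longer
travelling/milling bouts under impact) without claiming to reproduce any
particular field estimate. The state at each scan is drawn from the matrix
selected by the vessel presence of that scan's interval, so impact-labelled
pairs are exactly impact-matrix draws. The truth record stores the
matrices, their stationary vectors, bout lengths and recovery times
(computed with the estimation modules' own formulas) and the avoidance
coefficients; a (config, seed) pair determines every output byte.

What passing tests on this generator do *not* show: robustness to missing
fields, observer misclassification, serially correlated cohesion, unequal
scan spacing, or vessel effects that anticipate arrival (noise travels
ahead of vessels) — none of which the generator emulates.

## Numerical and scale choices

- Chi-square statistics are validated against a literal Σ(O−E)²/E oracle
  and `scipy.stats.chi2_contingency(correction=False)` to 1e−9.
- Row-stochasticity is enforced to 1e−12; `πP = π` to 1e−10.
- Reported minutes round half to even; tests always use unrounded values.
- Simulation scales in the test suite (500 replicates for type-I error
  calibration, 200 replicates of 50 groups × 40 observations for GLMM
  recovery, ~10⁵ transitions for end-to-end recovery, 100 replicates for
  selection consistency over the 8 subsets of {vessels, compliance, size})
  were chosen to give stable Monte-Carlo bounds at desk scale.
- Recovery bounds on transition probabilities use the family-wise
  (Bonferroni over 50 cells) analogue of a per-cell 3-SE band, since a
  correct implementation violates a raw per-cell band with double-digit
  probability across 50 simultaneous comparisons.

## Known limitations

- The Laplace approximation is least accurate for few observations per
  group with extreme probabilities; no adaptive quadrature fallback is
  provided.
- The avoidance model ignores temporal autocorrelation within follows
  beyond the group-level intercept, and no multinomial
  attraction-vs-neutral model is offered.
- The Markov model is first-order and unconditional: no covariate-dependent
  or hidden-state transitions.
- Degrees of freedom in the global chain test depend on the empty-cell
  policy (drop zero-combined-count columns per row); with sparse field data
  other reconstructions are conceivable.
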