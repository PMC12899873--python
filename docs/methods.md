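# Methods

This note documents the statistical model behind `dccn`, the choices made
where the design was genuinely open, and what the synthetic-data
validation does and does not demonstrate.

## Cohort model and exclusions

The unit of analysis is a participant with per-visit food-group intakes
(servings/day, ~45 groups), per-visit total energy (kcal/day), baseline
covariates, an incident-disease flag and person-years of follow-up.
Exclusions follow the usual prospective-cohort cascade, applied in a fixed
order so that logs are deterministic: prevalent disease (anti-diabetic
medication or fasting glucose ≥ 126 mg/dL, inclusive), missing dietary
data, baseline energy at or beyond the 0.5th/99.5th percentile band
(linear-interpolation percentile estimator, configurable), then any
missing key covariate. Percentile trimming is applied after the
prevalent-disease exclusion; the order is configurable. Note that
re-applying percentile trimming to its own output would trim a fresh tail
of the reduced sample — the operation is idempotent only with fixed
bounds, which is why the exclusion log records the kcal bounds actually
used and `apply_exclusions` accepts them back.

Cumulative-average intake reduces measurement error by averaging all
dietary assessments taken strictly before diagnosis or censoring
(`multi_visit`), or, for two-assessment designs, baseline only when the
diagnosis precedes the follow-up assessment (`baseline_plus_one`).

## Network construction

Edge weights are partial Spearman correlations: all variables (the two
foods and the covariates — total energy and sex, female = 1) are
rank-transformed with average ranks for ties, the food ranks are
residualized on the ranked covariates plus intercept by least squares,
and the Pearson correlation of the residuals is taken. Significance uses
the t reference with df = n − 2 − k. Ranks rather than raw intakes make
the edge weight robust to the heavy right skew of servings/day data;
zero-inflation shows up as tied blocks of average ranks.

Stability selection draws one 50% subsample of the group *dataset* per
iteration (100 iterations, without replacement; with-replacement
bootstrap available as a flag), shared by all food pairs. Sharing the
subsample across pairs mirrors dataset-level subsampling and allows the
full correlation matrix of an iteration to be computed in one vectorized
rank-residualization pass, which is what makes 100 iterations × ~1,000
pairs × two groups run in about a second at n = 2,000/group. An edge is
retained iff |mean signed r across iterations| > 0.2 and p < 0.05 in all
iterations. Sign consistency across iterations is reported as a
diagnostic but not required. The retention threshold is read on the mean
signed correlation; per-iteration significance uses the t approximation
(exact permutation tests are pointless at these sample sizes). A food
that is constant in every subsample stays in the node set as an isolate
with a logged warning.

Sensitivity sweeps (`threshold_sensitivity`) re-derive edge sets for a
grid of thresholds (0.15–0.30) and iteration counts (50–100) from a
single stored run and report Jaccard overlap with the default
configuration; edge sets are nested in the threshold by construction.

## Differential subnetworks

Edge identity is the unordered food pair; weights play no role in
membership. Shared edges are removed, and each exclusive edge set induces
a subgraph carrying the weights of its source network. Ego networks are
hop-based (unweighted distance ≤ 2 by default); graph summaries are
average degree 2E/N, density 2E/(N(N−1)) and global transitivity.

## Centralities and roles

Degree, strength (Σ|w|), betweenness (normalized, Brandes), closeness and
eigenvector centrality are computed on the absolute-weight graph;
negative edges (the staple food's substitution edges) keep their sign for
scoring and display, but no centrality definition for signed graphs is
assumed — |w| preserves the interaction-strength reading. Shortest-path
measures use distance 1/|w| (stronger co-consumption = closer). Closeness
is (number of reachable others)/(sum of distances to them), computed per
component, 0 for isolates. Eigenvector centrality is a power iteration on
the |w| adjacency of the largest component, shifted by the identity (same
Perron vector; breaks the ±λ oscillation on bipartite graphs), scaled to
maximum 1, zero elsewhere; non-convergence after 10,000 iterations is an
explicit error. z-scores use the population SD across the subnetwork's
nodes (a flag widens this to all foods); zero-variance columns are set to
0 rather than dropped so the integrated value remains a mean of exactly
five components. Ranks break ties lexicographically by food name. Role
labels are assigned hierarchically: primary hub (rank 1 and eigenvector
≥ 0.8), hub food (ranks 2–3), bridge (betweenness ≥ 0.15), connector
(degree ≥ 2), else peripheral.

## Scores

Adaptive binarization handles zero inflation per food: the cut-point is
Q1 if Q1 > 0, else the median if positive, else Q3 if positive, else any
positive amount counts as consumption (equivalently, cut-point 0).
Quartiles use linear interpolation (nearest-rank available). A value
*equal* to the cut-point codes 0 — the strict inequality matters because
staple foods carry heavy ties at the quartiles, and it is therefore fixed
and documented rather than configurable. Cut-points are computed on the
cohort's combined scoring population (not per outcome group), since
scoring must be possible prospectively. The two network scores are
weighted sums of the binary vector with the respective subnetwork's
integrated centralities (negative weights used as-is); foods absent from
a weight map contribute 0. Cross-cohort transfer recomputes cut-points in
the target cohort and applies the source cohort's weights, with a strict
or drop-missing policy for unmatched foods and an optional name map.

## Association model

The incident outcome is binary, so rate ratios come from a modified
Poisson model: Poisson GLM with log person-years offset, fitted by IRLS
(statsmodels), with HC0 sandwich variance (HC1 configurable; n is large
in all intended uses) and Wald 95% CIs (±1.96 robust SE). Exposure is
either the quartile indicators (Q1 reference; quartile boundaries at the
25/50/75 linear-interpolation percentiles, ties falling into the lower,
closed-right interval) or a single continuous term. The trend test refits
with the per-quartile median score as one continuous covariate and takes
a robust Wald p. The full adjustment set is age, sex, higher education,
regular exercise, smoking as two indicators (never = reference; a single
current-smoker flag is a config option), alcohol (unit-agnostic
continuous, declared in config), BMI and total energy.

## Synthetic cohorts

The generator exists to give every stage ground truth; its defaults are
the reference study conditions, fixed once:

- **Marginals.** One shared family: zero-inflated log-normal. Zero
  inflation is implemented by thresholding the latent Gaussian coordinate
  (not independent Bernoulli), so zeros carry correlation information, as
  real non-consumption does. The staple food has zero inflation 0,
  location log 2.8 servings/day and small σ (rice-like); rare foods have
  zero inflation up to 0.8.
- **Dependence.** A Gaussian copula per outcome group. The shared
  backbone in both groups: a staple food with latent ρ = −0.3 to five
  side-dish foods (substitution), two side-dish blocks at ρ = 0.5. Group
  differences are four diabetic-only and four non-diabetic-only disjoint
  pairs at latent ρ = 0.4. A one-off copula calculation fixed these
  values: latent 0.4 maps to an observed rank correlation of ≈ 0.33–0.38
  under the configured zero inflation, comfortably above the 0.2
  retention threshold, while latent 0 pairs sit at ≈ 0.
- **Energy and sex.** Energy is a caloric-density-weighted sum of intakes
  plus noise (so the energy adjustment in the network stage is active);
  sex and the other covariates are drawn independently of intake with
  cohort-realistic frequencies (63% female, mean age 58 ± 10, BMI
  24.3 ± 3.1).
- **Outcome.** Follow-up is truncated normal 5.8 ± 3.9 years (min 0.5);
  the baseline rate is 0.0099 events/person-year (≈ 9.9/1000 py). The
  planted adherence score is a weighted sum of binarized intake (+1 on
  diabetic-specific foods, −1 on non-diabetic-specific foods), binarized
  by the same adaptive rules used for scoring. In `score_rate` mode the
  event waiting time is exponential with rate = baseline ×
  exp(log 1.5 per SD of the standardized score), censored at end of
  follow-up, and person-years accrue to diagnosis or censoring — so the
  Poisson/offset analysis is exactly well-specified and the fitted IRR
  per SD is centered on the planted 1.5. In `group_label` mode the
  incident flag *is* the simulation group, giving exact stratification
  ground truth for network recovery. The two modes exist because a single
  draw cannot make the group-specific copulas and a score-driven outcome
  both exact simultaneously.
- **Seeds.** One master seed expands into fixed per-stage child streams
  (intake, outcome, covariates), so stages are independently
  reproducible; identical seeds give bitwise-identical data.

What passing the synthetic checks does **not** show: the generator has a
single marginal family, no measurement error in the intake instrument, no
intake–covariate confounding, covariates independent of diet, and a
differential structure planted in *correlations with equal marginals* —
so D_CCN carries no marginal signal in `group_label` mode by design.
Real-data performance (FFQ error, culture-specific food groupings,
confounded covariates) is outside what these simulations can establish.

## Validation problem sizes

Chosen once as the reference conditions: differential-edge recovery uses
20 replicate cohorts at 2,000/group with default stability parameters
(median sensitivity and false-exclusive count reported); effect recovery
uses cohorts of n = 20,000 with the median over five independent
replicates reported to damp single-draw Monte-Carlo noise (the
single-cohort estimate is the one-replicate case); null CI coverage uses
500 replicates at n = 2,000. Smaller sizes appear in unit tests purely as
smoke checks.

## Known limitations

- The closeness convention (reachable/Σdistance on 1/|w| distances) is
  one of several in circulation; published tables using other conventions
  are not directly comparable, so closeness magnitudes should only be
  compared within runs of this package.
- Stability selection controls selection stability, not FWER/FDR; the
  all-iterations-significant rule is conservative but has no formal
  error-rate guarantee.
- The modified Poisson model treats the binary outcome with a person-time
  offset; with long follow-up and high cumulative incidence the rate
  interpretation degrades (events here are rare, ~6% cumulative).
- Hypergeometric module detection and regularized graphical models are
  deliberately out of scope.
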