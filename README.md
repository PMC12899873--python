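# dccn — differential food co-consumption networks

`dccn` implements a differential-network framework for dietary epidemiology:
it asks not *how much* of each food people eat, but *which foods are eaten
together*, and whether those co-consumption structures differ between people
who go on to develop a disease (the running example is incident type 2
diabetes) and those who do not. It is aimed at nutritional epidemiologists
working with prospective cohort data — food-frequency-questionnaire intakes
in servings/day, incident-disease flags and person-years of follow-up.

## Method

1. **Co-consumption networks.** For each outcome group, an undirected
   weighted graph over the food groups. The weight of edge (i, j) is the
   partial Spearman correlation of intakes, adjusted for total energy and
   sex, estimated with stability selection: the group is subsampled at 50%
   without replacement 100 times, and the edge is kept only if
   |mean r across iterations| > 0.2 and p < 0.05 in **every** iteration.
2. **Differential subnetworks.** Edges shared by both group networks are
   removed; the edge-induced subgraphs on the disease-exclusive and
   control-exclusive edges isolate the disease-specific structure.
3. **Integrated centrality.** Per node, five measures — degree, strength
   (Σ|w|), betweenness, closeness, eigenvector — are z-standardized across
   the subnetwork and averaged. Nodes are ranked and classified
   hierarchically: primary hub (rank 1, eigenvector ≥ 0.8), hub food
   (ranks 2–3), bridge (betweenness ≥ 0.15), connector (degree ≥ 2),
   peripheral.
4. **D_CCN score.** Each participant's intake is binarized per food with
   an adaptive cut-point (Q1 if non-zero, else the median, else Q3, else
   any positive amount), then

   D_CCN = Σ_f b_f · w_D(f) − Σ_f b_f · w_ND(f),

   where w_D, w_ND are the integrated centralities of the disease- and
   control-exclusive subnetworks. Weights learned in one cohort can be
   transferred to another (cut-points recomputed in the target cohort).
5. **Association.** Incidence rate ratios across cohort-specific D_CCN
   quartiles by modified Poisson regression — a Poisson GLM on the binary
   incident outcome with log person-years offset and HC0 sandwich
   variance — plus a trend test on the per-quartile median score.

Because real cohort data of this kind is access-restricted, the package
ships a synthetic cohort generator (Gaussian copula with latent
thresholding for zero inflation, log-normal marginals, planted
group-specific edges, and a planted score→outcome effect) so that every
stage can be validated against known ground truth. See
`docs/methods.md` for modelling details and design choices.

## Worked example

Run the whole workflow on a planted synthetic cohort (2,000 per group,
45 foods, four diabetic-only and four non-diabetic-only planted edges):

```python
from dccn import pipeline
pipeline.run_all({
    "seed": 1, "out_dir": "demo",
    "simulate": {"n_diabetic": 2000, "n_non_diabetic": 2000},
})
```

or equivalently `dccn run --config demo.yaml`. The run writes, per stage,
`cohort_full.csv`, `exclusion_log.json`, `cumavg.csv`,
`edges_<group>.csv` / `.graphml`, `diff_<group>.csv`,
`centrality_<group>.csv`, `scores.csv`, `irr.json` and a `manifest.json`
of content hashes. With seed 1 the exclusion stage trims 40 of 4,000
participants as energy outliers, and each group network recovers 35
edges — the 31 planted shared edges plus that group's 4 planted exclusive
edges, with the staple food's edges all negative:

```
food_a food_b    weight  sign  n_iterations_significant
food01 food02 -0.373087    -1                       100
food01 food03 -0.372711    -1                       100
```

`diff_summary.json` reports both differential subnetworks at 8 nodes and
4 edges — exactly the planted differential structure, with 31 shared edges
removed. Scores follow per participant:

```
participant_id  diabetes_score  non_diabetes_score     d_ccn quartile
       P000001       -0.284663            0.282986 -0.567649       Q1
       P000002        0.554274            0.024997  0.529277       Q4
```

To check the score→outcome chain, simulate an outcome driven by the
planted adherence score (rate = baseline × exp(log 1.5 per SD)) and refit:

```python
from dccn import evaluate
evaluate.irr_recovery(seed=7)
# {'irr_per_sd': 1.478..., 'trend_p': 1.3e-39, 'q4_vs_q1_irr': 2.45..., ...}
```

The fitted IRR per SD of the score (1.48, median over five cohorts of
n = 20,000) recovers the planted 1.5, and the quartile trend test is
decisive.

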