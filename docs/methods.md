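# Methods

This note documents the models, numerical choices and limitations of
`acceptmap`. It is written for users who need to know exactly what the
pipeline computes and what its tests do and do not establish.

## Data model

An *evaluation* is one observed medicine intake by one patient at one of
three timepoints (first intake after inclusion, 24 h later, last intake
of treatment). Nine categorical observational variables are recorded:

| variable | categories | positively connoted |
|---|---|---|
| result_intake | fully / partly / not_taken | fully |
| reaction | positive / neutral / negative (3-point facial hedonic scale) | positive |
| prep_admin_time | short (≤ 60 s) / medium (≤ 150 s) / long (> 150 s) | short |
| divided_dose, food_drink, alteration, extra_device, reward, restraint | no / yes | no |

21 categories in total. The time classes are boundaries on the summed
preparation + administration time: "one minute and less" is read as
inclusive at 60 s, and "more than 2 min 30 s" makes 150 s the last
medium value. Age groups (0–2, 3–5, 6–11, 12–17 completed years) are
derived from `age_years` at analysis time rather than stored, so they
cannot drift out of sync. Any observational cell may be missing (empty
CSV cell); metadata may not. Adherence is reported per patient at the
end of treatment as a band of the prescribed-dose percentage
(0–20 … 81–100) plus a difficulty flag.

## Multiple correspondence analysis

MCA is plain correspondence analysis of the N × 21 indicator matrix —
no Benzécri/Greenacre eigenvalue correction, which would rescale
reported inertia shares but not coordinates. With Q = 9 variables, row
masses are uniform and total inertia is J/Q − 1 = 4/3, which the test
suite asserts to 1e-9 and uses as an internal consistency check.

Numerical choices:

* **Axis orientation.** The SVD sign indeterminacy is fixed by flipping
  each axis so that the category coordinate with the largest absolute
  loading is positive. Fits are then byte-deterministic.
* **Unobserved categories** are dropped with a warning rather than kept
  at zero mass (zero-mass columns are undefined in CA). Projection of a
  supplementary row carrying mass on a dropped category is a hard error
  naming the category.
* **Supplementary projection** uses the transition formula
  f_s = (1/√λ_s) Σ_j (z_j/Q) g_{js}. It is linear in the (possibly
  fractional) indicator row, which gives two useful identities exploited
  by the tests: active rows re-project onto their own coordinates, and
  the expected position of a random evaluation from a category-probability
  profile is the projection of the probability vector itself
  (`population_barycenter`).
* Three dimensions are retained by default (`n_components=3`); the
  retained map is also the space in which clustering and scoring
  operate.

## Imputation of missing observational measures

Regularized iterative MCA, assuming values are missing completely at
random: initialize each missing cell with the observed category
proportions of its variable, then iterate {CA fit on the fuzzy table →
rank-S reconstruction with singular values shrunk by the mean of the
trailing eigenvalues (floored at 0) → overwrite only originally-missing
cells → clip to [0, 1] and renormalize each imputed per-variable block
to sum to 1} until the largest change on a missing cell falls below
`tol` (defaults S = 3, tol = 1e-6, max_iter = 1000; non-convergence
returns the last iterate with `converged=False` and a warning).
Observed cells are never modified and the procedure is equivariant under
row permutation. Hard calls are per-variable argmax with ties broken by
codebook order.

Two caveats found during development and reflected in the tests:

* When the completed data matrix has rank ≤ S, the rank-S reconstruction
  reproduces *any* initialization exactly, so every initialization is a
  fixed point. On such (artificial, block-structured) data a smaller S
  must be used for the structure to pull imputed cells; real survey data
  have rank well above 3.
* The achievable hard-call accuracy is bounded by the Bayes-modal
  ceiling — even knowing each row's latent profile one can only call the
  profile's modal category. Under the default synthetic profiles that
  ceiling is ≈ 0.77 at 10% MCAR; the imputer reaches ≈ 0.72 on a
  500-evaluation corpus, and the regression test asserts accuracy within
  0.08 of the computed ceiling and above 0.70.

## Clustering and zones

Hierarchical clustering on the retained three map dimensions (Ward
linkage, Euclidean), tree cut at k = 2, then a single k-means run
seeded from the cut's cluster means — deterministic, and never worse in
within-cluster sum of squares than the raw cut. Clusters are
characterized by the v-test: for a category held by n_j of N
evaluations, n_kj of them inside a cluster of size n_k, the
hypergeometric two-sided tail p = min(1, 2·min(P(X ≥ n_kj),
P(X ≤ n_kj))) is mapped through the normal quantile,
v = sign · Φ⁻¹(1 − p/2), with p floored at the smallest positive float.
This form reduces to v = 0 when the "cluster" is the whole dataset and
is antisymmetric under complementation; |v| > 1.96 flags significance.
The cluster whose significant over-representations contain more
positively connoted measures is labelled "Positively accepted" (green),
ties broken by the larger share of fully-taken intakes; a partition with
no significant enrichment anywhere is rejected as not meaningful.

The published method draws green/red *areas* on the map without
defining their boundary; here the zone of any point is that of its
nearest consolidated centroid — the unique parameter-free rule
consistent with k-means consolidation (every training evaluation's zone
agrees with its cluster label). Exact ties break toward green.

## Acceptability scores

A score is the barycenter (unweighted mean) of a set of supplementary
coordinates, with a confidence ellipse of the mean per dimension pair:
center m, shape S/n (unbiased sample covariance over n), squared radius
q. For q we use the Hotelling-T² quantile 2(n−1)/(n−2)·F₂,ₙ₋₂(level)
rather than the asymptotic χ²₂ quantile: with the covariance estimated
from the same n evaluations the χ² ellipse systematically undercovers
(measured ≈ 0.873 at n = 58 for level 0.90; the T² ellipse measures
≈ 0.88–0.90). The χ² construction remains available via
`method="chi2"`. Residual undercoverage of a point or two below nominal
comes from the skewness of projected 58-draw multinomial samples and is
inherent to the study-sized n, not a coding artifact.

Classification mirrors how the three 2D panes of the map are read: the
medicine is accepted iff the barycenter is in green and, in each pane,
all boundary points of the ellipse (360 by default, uniform in angle,
third coordinate held at the barycenter) are in green. Score comparison
declares two scores significantly different iff their ellipses are
disjoint in *every* pane; disjointness is decided numerically by testing
containment of each ellipse's center and sampled boundary (720 points)
in the other, tangency counting as overlap (inclusive membership with
relative tolerance 1e-9). Scores from fewer than 30 patients are
computed but flagged `reliable=False` with a warning, so small subgroup
analyses (e.g. a 7-patient adolescent group) remain possible with the
appropriate caveat.

## Contingency tables and tests

Test selection follows the expected-count screening rule: Pearson's χ²
(no continuity correction) when at least 80% of expected counts are ≥ 5
and none is zero, Fisher's exact test otherwise. All-zero rows are kept
in reports but dropped before testing (their expected counts would be
zero, leaving both tests undefined); variables with no variation get no
test. The r×c Fisher test is the Freeman–Halton generalization: all
tables with the observed margins are enumerated recursively and the
p-value sums the multivariate-hypergeometric probabilities of tables no
more probable than the observed one, with a relative tie tolerance of
1e-12 on probability comparisons; enumeration beyond a configurable cap
(default 2·10⁶ visited nodes) raises a capacity error rather than
stalling. Percentages in report replicas are rounded half-away-from-zero
to integers and computed on non-missing denominators.

One discrepancy is documented rather than papered over: applied to the
published by-age outcome table, the stated selection rule chooses Fisher
for three rows (reaction, preparation/administration time, food/drink)
where the publication prints χ², although the same rule reproduces every
flag of the over-time table and the remaining by-age flags. No
expected-count threshold reproduces all printed flags simultaneously
(the over-time and by-age reaction rows have comparable expected-count
profiles but different printed tests). The implementation follows the
stated rule; the corresponding acceptance tests for those three rows
fail and are left failing.

The two published outcome tables are also mutually inconsistent in their
missing-data tallies (170 vs 167 non-missing reactions; 149 vs 146
times), so no single row-level dataset can reproduce both.
`acceptmap.datasets` therefore ships the published counts as separate
table inputs, plus a synthetic row-level reconstruction that matches the
over-time marginals exactly (its joint structure is invented — the
publication prints only marginals — and its docstring says so).

## Synthetic data generator

The generator emulates the study conditions: a reference corpus of
2,611 evaluations (the published pool size) drawn i.i.d. from a
two-profile mixture, and per-medicine sets of 58 patients × 3 timepoints
with the patient's latent profile persisting over time. Default
parameters, chosen once: mixture weight 0.6 for the positive profile;
the positive profile puts ≥ 0.85 mass on every positively connoted
category (0.90/0.07/0.03 for intake result, 0.92/0.08 for the binary
variables); the negative profile puts the majority of its mass on
negatively connoted categories of intake result, reaction and restraint
(e.g. 0.20/0.40/0.40 for intake result). Patient metadata mirror the
study population: age-group weights 11/24/16/7, 72% boys, 90% first
exposure, dosing frequency 3/day for 76%, treatment duration 3–14 days.
Missingness, when requested, is injected MCAR per cell — matching what
the imputation stage assumes. Latent labels are retained on generated
sets for recovery tests and never serialized to CSV.

Variables are conditionally independent given the latent profile. This
is the simplest structure in which profile membership drives all
associations between the 21 measures, and it is a real limitation: real
evaluations carry residual within-profile dependence (e.g. restraint and
negative reaction co-occurring beyond what the profile explains),
country/culture covariates, and product-level clustering, none of which
the generator emulates. Passing recovery tests therefore demonstrate
that the pipeline recovers planted structure of this conditional-
independence form — not that the published framework itself is
reproduced. The published map geometry cannot be reproduced without the
original corpus; the mapping layer is validated through properties
(inertia identities, projection oracles, coverage simulations, ARI ≥
0.9 recovery of well-separated profiles) instead.

## Problem sizes used by tests and the acceptance script

Chosen to exercise the asymptotics that matter while staying quick on a
single CPU: reference corpora of 600 (shared test fixture), 1,000
(profile recovery), 2,000 (coverage experiment) and 2,611 (worked
example, default); 1,000 replicates of 58 evaluations for the coverage
estimate; exhaustive v-test enumeration for all margins with N ≤ 30;
full Freeman–Halton enumeration for the published tables (≤ ~10⁶
nodes). The whole suite runs in well under a minute.
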