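# Methods

`netsweep` implements a graph-theoretical analysis of resting-state
functional brain networks of the kind used to compare antidepressant
treatment responders with non-responders and to predict response from
pre-treatment network topology. This note records the models, the
conventions fixed where the literature leaves choices open, and what the
synthetic-data generator does and does not emulate.

## Network construction

Each subject contributes a cleaned regional BOLD time-series matrix
(T timepoints × N regions; the default parcellation is AAL-90 with
T = 230 volumes). Functional connectivity is the N × N Pearson
correlation matrix of the regional time series with the diagonal stored
as zero — self-connections are never edges, and zeroing them up front
removes a special case from thresholding. No Fisher z-transform is
applied: thresholding is rank-based, and a monotone transform cannot
change edge ranks.

A sparsity threshold s retains the top s·N(N−1)/2 connections as
unweighted, undirected edges. The sweep covers s = 0.10 to 0.34 in
steps of 0.01 (25 graphs). Conventions fixed for bit-reproducibility:

- **Ranking** is by signed weight descending, so strong negative
  correlations enter last (an absolute-value mode is available behind a
  flag for users who prefer magnitude thresholding).
- **Edge count** is round-half-up of s·N(N−1)/2.
- **Ties** at the cut break by ascending (i, j) lexicographic order —
  deterministic without randomness.

Because edges are chosen by rank, the sweep's edge sets are nested;
every metric curve is evaluated on graphs that only gain edges as s
grows.

## Topological metrics

Global: clustering coefficient Cp, characteristic path length Lp,
global efficiency Eglob, local efficiency Eloc, assortativity,
modularity Q, and the small-world triple γ = Cp/⟨Cp_null⟩,
λ = Lp/⟨Lp_null⟩, σ = γ/λ. Nodal: degree centrality, nodal efficiency,
betweenness (unnormalized unordered-pair counts — any fixed
normalization cancels in group contrasts), and clustering.

Degenerate cases are defined as follows. Nodes with degree < 2 have
clustering 0 and contribute 0 to local efficiency. Efficiency-type
metrics treat unreachable pairs as 1/∞ = 0. Lp averages over *connected
ordered pairs only*; this matters on fragmented low-sparsity graphs,
where the convention changes λ, and is therefore stated prominently:
users comparing against tools that substitute a finite penalty distance
for unreachable pairs will see different Lp/λ at low sparsity.

Betweenness uses shortest-path dependency accumulation (the standard
linear-per-source scheme), shortest paths are breadth-first,
assortativity is the Pearson correlation of degrees across both
orientations of every edge (undefined, NaN, when all degrees are equal,
as on complete graphs and rings).

Modularity is the best Q over 10 seeded runs of a Louvain-style greedy
optimizer (local moving plus aggregation); run seeds derive from one
`SeedSequence`, so best-of-k is exactly monotone in k and reproducible.

The null ensemble for γ and λ consists of degree-preserving surrogates
generated by Maslov–Sneppen double-edge swaps: 10 attempted swaps per
edge, proposals creating self-loops or duplicate edges rejected, so
every surrogate keeps the exact degree sequence. The default ensemble
size is 100 per graph (configurable); at 90 nodes this keeps γ/λ
ensemble noise well below group differences of interest. Graphs that
admit no valid swap (stars) are returned as copies with a warning.

Every metric curve is integrated over the sweep with the trapezoid rule
into a threshold-insensitive AUC scalar; the AUC of a constant unit
curve over the default sweep is 0.24, which fixes the scale of all AUC
values (an AUC of x corresponds to a mean per-threshold value of
x/0.24).

## Group inference

AUC metrics are compared between groups with a nonparametric
permutation test: pooled values are re-partitioned into groups of the
original sizes (default 10,000 permutations), the mean difference
recomputed each time, and the 95th percentile of the *absolute* null
differences used as the critical value of a two-tailed test at
α = 0.05 — the only reading under which a "95th percentile, two-tailed"
rule actually has size 0.05. Reported p-values use add-one smoothing,
p = (1 + #{|null| ≥ |observed|})/(n_perm + 1), the standard
Monte-Carlo correction that avoids p = 0.

Nodal p-values are Benjamini–Hochberg FDR-adjusted within each nodal
metric family (90 tests per metric); both raw and adjusted values are
reported. Global metrics are not multiplicity-corrected.

Degree distributions (extracted at the sweep midpoint, s = 0.22, by
default) and link-weight distributions (all N(N−1)/2 upper-triangle
weights of the full weighted matrix) are compared with two-sample
Kolmogorov–Smirnov (asymptotic) and Mann–Whitney U tests (exact
enumeration when both samples have ≤ 20 tie-free values, normal
approximation with continuity and tie correction otherwise).

## Clinical models

Subjects are responders when their 17-item Hamilton Depression Rating
Scale (HAMD-17) score falls by ≥ 50% from pre- to post-treatment; the
boundary counts as response, and worsening (negative reduction) is a
valid non-response.

Partial correlations between topology indices and symptom change
residualize both variables on age and sex (with intercept) by least
squares; significance uses t = r·sqrt(df/(1−r²)) with
df = n − 2 − n_covariates.

Prediction uses forward likelihood-ratio binary logistic regression:
candidates enter by the smallest likelihood-ratio χ² p-value below 0.05
and leave when their removal p exceeds 0.10 (the conventional defaults
for this selection style; both configurable). Maximum likelihood is by
Newton/IRLS with step halving, convergence tolerance 1e−8 on the
log-likelihood, at most 100 iterations; perfect separation is detected
(diverging coefficients with step halving exhausted) and reported as an
error naming the separating feature. Odds-ratio confidence intervals
are Wald, matching the usual OR (95% CI) reporting convention.
Internally features are standardized for conditioning; coefficients are
mapped back to the original scale. The candidate pool is passed in
explicitly (in the pipeline: the metrics significant in the group
comparison, nodal ones after FDR) so the inferential chain stays
visible. Sex is coded 0 = male, 1 = female; this affects only the
intercept.

ROC curves sweep all distinct score thresholds (predict positive at
score ≥ threshold), AUC is trapezoidal over (1−specificity,
sensitivity), and the reported operating point maximizes Youden's
J = sensitivity + specificity − 1 with ties broken toward higher
specificity. Constant scores degenerate to the chance diagonal,
AUC 0.5 by convention.

## Synthetic cohort generator

No public dataset accompanies the study design this package targets, so
the generator plants known effects in data with the right structure.
ROIs are partitioned into 6 equal modules; each group's model
correlation matrix has `within_module_r` inside modules and
`between_module_r` elsewhere (repaired to the nearest positive
semi-definite correlation matrix by eigenvalue clipping and diagonal
rescaling if a configuration requires it — the default blocks are
already PSD). A block-correlation model was chosen because the
within/between contrast directly manipulates clustering, local
efficiency and modularity — exactly the segregation metrics on which
treatment non-responders are reported to score higher — so the planted
effect is recoverable by the downstream machinery being tested.

Defaults: responders within/between = 0.32/0.12; non-responders
0.335/0.115 (more segregated); observation noise SD 0.5 per channel
(attenuating all observed correlations equally); T = 230; group sizes
37/32. With these settings the non-responder-minus-responder AUC
differences are positive for γ, Eloc, modularity and σ with
standardized effects of roughly d ≈ 1.3–1.6 — large enough for the
permutation test to detect AUC-modularity with high power at n = 69,
small enough that subject-level overlap remains substantial. The
parameters were calibrated once against these design targets and then
frozen.

Clinical scores: age uniform on 13–18, sex Bernoulli(0.5) (an optional
confounded mode ties both mildly to group for testing covariate
adjustment), pre-treatment HAMD-17 ~ Normal(18.4, 5.5) truncated at ≥ 8
(the > 7 inclusion criterion) and rounded to integers, HAMA
~ Normal(15.4, 6.7) truncated at ≥ 0. Post-treatment scores apply a
reduction rate drawn uniformly from the group's range — responders
(0.60, 0.95), non-responders (−0.15, 0.35). Since integer rounding can
shift a realized reduction rate by at most 0.5/8 ≈ 0.0625 (pre ≥ 8),
ranges must keep that margin from the 0.50 boundary; the constructor
rejects configurations that could make derived labels contradict the
generating groups, and the generator asserts label consistency on every
cohort. HAMA post-treatment scores reuse the subject's HAMD reduction
draw plus Gaussian jitter (SD 0.1), reflecting that anxiety improvement
tracks depression improvement in treatment responders.

All randomness flows from one master seed: subject i uses child i+1 of
`SeedSequence(seed)` (child 0 drives the clinical table), so cohorts are
reproducible subject-by-subject and individual subjects can be
regenerated in isolation.

**What the generator does not emulate:** spatial autocorrelation and
hemodynamic smoothness of BOLD, heavy-tailed or heteroscedastic noise,
head-motion artifacts, true inter-subject variability in connectivity
structure (between-subject variance arises only from finite-length
sampling of the correlations), hub topology and the strong small-world
regime of real cortex (synthetic γ per threshold is ≈ 1.0–1.3 versus
≈ 2 in real connectomes), and any genuine coupling between network
topology and symptom scores — clinical variables are independent of the
time series given group. Passing tests therefore demonstrate that the
*machinery* (construction, metrics, normalization, inference,
selection) is correct and calibrated, not that the scientific effect
exists in any particular population.

## Problem sizes used by the validation suite

The test suite exercises full-size cohorts (90 ROIs, 230 volumes,
37/32 subjects) but scales Monte-Carlo depth to keep runs economical:
permutation-calibration uses 500 null cohorts × 2,000 permutations
judged on the AUC clustering coefficient (the machinery under test —
re-partitioning of subject-level AUC values — is shared by all
metrics); effect recovery uses 10 generator seeds with 10 nulls per
graph; selection operating characteristics use 40 seeds. The
acceptance script re-measures permutation-test calibration from scratch
with 500 datasets × 2,000 permutations. Defaults for real analyses
remain 100 nulls and 10,000 permutations.

## Known limitations

- Weighted, directed, and signed-layer network variants are out of
  scope; negative correlations only affect edge ranking.
- The permutation test is unadjusted for covariates (no
  Freedman–Lane-style schemes).
- Louvain is a heuristic; Q values are best-of-runs lower bounds on the
  true optimum, and group contrasts in modularity inherit that
  (seeded, hence reproducible) approximation.
- γ and λ depend on the null ensemble's size and rewiring depth;
  cross-package comparisons of absolute γ/λ values require matching
  those settings.
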