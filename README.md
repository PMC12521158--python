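# netsweep

Graph-theoretical analysis of resting-state functional brain networks,
built for treatment-response studies: who will respond to an
antidepressant, and what does their pre-treatment connectome look like?

`netsweep` is aimed at researchers analyzing ROI-level fMRI time series
(e.g. AAL-90 parcellations) who want a tested, reproducible
implementation of the standard analysis chain:

1. **Connectivity** — Pearson correlation between regional BOLD time
   series → weighted N × N functional connectivity matrix.
2. **Thresholding** — binarization across a sparsity sweep
   (default s = 0.10 … 0.34, step 0.01; nested edge sets, deterministic
   tie-breaking).
3. **Topology** — global metrics (clustering coefficient C_p,
   characteristic path length L_p, global/local efficiency
   E_glob/E_loc, assortativity, modularity Q) and nodal metrics (degree
   centrality, nodal efficiency, betweenness, clustering); small-world
   normalization γ = C_p/⟨C_p^null⟩, λ = L_p/⟨L_p^null⟩, σ = γ/λ
   against degree-preserving (Maslov–Sneppen) rewired null networks;
   trapezoidal AUC integration of every metric curve over the sweep.
4. **Inference** — two-tailed permutation tests on AUC metrics (null =
   re-partitioned group labels, critical value = 95th percentile of the
   absolute null), Benjamini–Hochberg FDR within each nodal-metric
   family, K-S and Mann–Whitney tests on degree and link-weight
   distributions.
5. **Clinical models** — responder labeling (≥ 50% HAMD-17 reduction),
   age/sex-adjusted partial correlations with symptom change, forward
   likelihood-ratio logistic regression over screened predictors, and
   ROC curves with Youden-optimal operating points.

A synthetic-cohort generator (block-correlation multivariate-normal
model with a plantable segregation effect and matched clinical scores)
makes the whole chain testable end to end without scan data. Graph
metrics are implemented independently (numpy + numba) and validated
against networkx and exhaustive enumeration to 1e-9.

See `docs/methods.md` for the model conventions (disconnected-pair
handling, tie rules, null-ensemble settings) and the generator's scope.

## Worked example

Run the full pipeline on a simulated 69-subject cohort (37 responders,
32 non-responders, 90 ROIs, 230 volumes, planted segregation effect in
the non-responders):

```bash
netsweep run-all --seed 1          # or: python -m netsweep.cli ...
```

which prints (seed 1, ~7 minutes on one CPU):

```
netsweep 0.1.0 run report (seed=1)

Global topological metrics (AUC over sparsity sweep)
----------------------------------------------------------------
Cp             nonresponder: 0.1409 ± 0.0040  responder: 0.1327 ± 0.0036  p=0.0001 *
Lp             nonresponder: 0.5021 ± 0.0107  responder: 0.4876 ± 0.0073  p=0.0001 *
Eglob          nonresponder: 0.1354 ± 0.0012  responder: 0.1372 ± 0.0008  p=0.0001 *
Eloc           nonresponder: 0.1846 ± 0.0024  responder: 0.1795 ± 0.0023  p=0.0001 *
gamma          nonresponder: 0.7129 ± 0.0404  responder: 0.6404 ± 0.0365  p=0.0001 *
lambda         nonresponder: 0.2695 ± 0.0054  responder: 0.2622 ± 0.0036  p=0.0001 *
sigma          nonresponder: 0.6108 ± 0.0233  responder: 0.5700 ± 0.0251  p=0.0001 *
assortativity  nonresponder: 0.0242 ± 0.0132  responder: 0.0220 ± 0.0139  p=0.4840
modularity     nonresponder: 0.1230 ± 0.0032  responder: 0.1165 ± 0.0031  p=0.0001 *

Selected predictors: ['Cp', 'modularity', 'gamma']
  ROC[joint_model]: AUC=0.955 sens=1.000 spec=0.781
  ROC[Cp]: AUC=0.938 sens=0.946 spec=0.812
  ROC[modularity]: AUC=0.923 sens=0.784 spec=0.938
  ROC[gamma]: AUC=0.905 sens=0.784 spec=0.906
```

Reading the output: each row is a metric's AUC over the sparsity sweep,
mean ± SD per group (an AUC of x corresponds to a mean per-threshold
value of x/0.24). The generator plants higher network segregation in
non-responders, and the permutation test recovers it: clustering, local
efficiency, γ, σ and modularity are all higher in the non-responder
group (p = 0.0001 is the add-one floor at 10,000 permutations), while
assortativity — in which no effect was planted — stays null. The
forward-LR step then selects segregation metrics as response
predictors; ROC rows give each predictor's discrimination (AUC) and the
sensitivity/specificity at the Youden-optimal cutoff. Because planted
group covariances drive every subject's data, these synthetic effects
are far cleaner than anything real cohorts produce.

All intermediates (per-subject time series TSVs, connectivity CSVs,
metric curves, AUC tables, comparison tables, partial correlations,
logistic model, ROC curves, JSON report) are persisted under the output
directory; every number in the report can be recomputed from them.
Stages are also available individually (`netsweep simulate | connect |
metrics | compare | clinical`) and as library functions
(`netsweep.compute_fc_matrix`, `netsweep.metrics_for_subject`,
`netsweep.permutation_test`, `netsweep.forward_lr_logistic`, …).

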