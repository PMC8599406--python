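# evodet — determinants of gene sequence-evolution constraint

`evodet` is an analysis pipeline for a classic question in molecular
evolution: **which gene-level variables determine how strongly purifying
selection constrains a protein-coding sequence?** It targets the setting of
a fission-yeast–style gene table — a few thousand genes described by ~170
genomic, proteomic and functional variables organised in named groups
(expression, gene/protein size, amino-acid composition, GO-slim membership,
chromosome, protein–protein interaction network centrality) — with one or
two per-gene constraint responses: a *dN*-like substitution rate (high =
fast evolution) and a *phyloP*-like conservation score (high = conserved).

The pipeline combines three complementary views of variable influence:

- **Partial least squares (PLS) regression** with cross-validated component
  selection, interpreted through **VIP** (variable importance in
  projection): VIP_j = √(p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a), where SS_a
  is the share of response variance explained by component *a* and w_a its
  weight vector. Mean VIP² over variables is 1; VIP < 1 is conventionally
  removable.
- **Principal-components regression (PCR)** with a per-variable **variance
  decomposition**: contribution_j = Σ_a p_ja² SS_a over orthonormal
  loadings, which sums exactly to the training R².
- **Grouped Spearman partial correlations**: each variable's rank
  correlation with constraint, controlling for all variables *outside* its
  own group, Bonferroni-adjusted per response.

A 500-tree random-forest baseline (mtry = p/3) provides a model-class
comparison, scored like the rest via RMSE and pseudo-R² = 1 − MSE/var(y) on
a 30% holdout. Network centralities (degree, closeness, betweenness,
eigenvector; functional and physical networks) are computed from
STRING-format edge lists thresholded at a combined score of 0.400.

Because the package is exercised end-to-end on synthetic studies, it ships a
first-class generator (`evodet.simulate`) that plants known structure —
informative variables with signed coefficients, a degree-linked network
effect, a target holdout R² calibrated in closed form — so every claim the
pipeline makes can be checked against ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on a generated
dataset (2,576 genes, ~170 variables, 15 planted informative variables,
planted holdout R² = 0.5):

```bash
python analysis/01_simulate.py
python analysis/02_network_features.py
python analysis/03_fit_models.py
python analysis/04_partial_correlations.py
python analysis/05_forest_comparison.py
python analysis/06_recovery.py
```

Output of steps 03–06 on the default seed:

```
dN: PLS 49.8% (A=2), PCR 49.1% (A=5) of holdout variance explained
  top VIP: expr_15=3.68, expr_29=3.65, expr_26=3.64
phyloP: PLS 14.7% (A=1), PCR 14.1% (A=3) of holdout variance explained
dN: 19/166 variables significant (Bonferroni-adjusted p < 0.05)
  strongest: expr_06 rho=-0.569
sign flip dN vs phyloP among dN-significant variables: 19/19
response  PLS  PCR   RF
      dN 49.8 49.1 47.6
  phyloP 14.7 14.1 14.4
VIP recall@15: 1.00; partial-correlation sign agreement: 1.00
holdout R^2 gap to planted 0.5: pls=0.002, pcr=0.009
```

Reading this: both latent models recover essentially all of the planted 50%
of dN variance (the phyloP-like response is a noisier negative copy, so its
ceiling is far lower); every planted expression variable is flagged by VIP >
1 and correlates negatively with the rate-like response but positively with
the conservation-like one — the sign flip expected from the two responses'
opposite orientation; and the forest baseline lands in the same range as the
linear latent models, as it should when the planted signal is linear.

Library use without the scripts:

```python
from evodet import (AnalysisConfig, SyntheticSpec, generate_synthetic_study,
                    load_string_edges, run_study)

ds = generate_synthetic_study(SyntheticSpec(), seed=7)
paths = ds.write("study/")
functional = load_string_edges(paths["functional"], 0.400, "4896.")
physical = load_string_edges(paths["physical"], 0.400, "4896.")
report = run_study(ds.table, functional, physical, AnalysisConfig())
report.metrics["dN"]["pls"].variance_explained
```

A `evodet` command-line interface wraps the same functions
(`evodet simulate`, `evodet run`, `evodet centrality`, `evodet pcor`,
`evodet importance`).

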