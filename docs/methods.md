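# Methods

This note documents the models implemented in `evodet`, the choices made
where the design was genuinely open, and what the synthetic studies do and
do not demonstrate.

## Data model and preprocessing

A study is a genes × variables table with per-variable *group* labels
(expression, size, amino_acid_composition, GO_*, chromosome,
network_centrality) and *kind* (continuous/binary/categorical), plus one or
two response vectors kept strictly outside the predictor matrix. Two
response conventions are supported simultaneously: a rate-like response
(higher = less constrained, dN-style) and a conservation-like response
(higher = more constrained, phyloP-style).

Preprocessing order: one-hot encoding of categorical/membership columns
(all levels kept — the latent models tolerate the resulting collinearity,
and dropping a reference level would hide one GO term or chromosome from
the importance tables); amino-acid counts rescaled to per-gene proportions
(rows sum to 1 within 1e-12); network centralities merged; imputation;
train/test split; centring and scaling.

**Centring/scaling.** Per-variable mean and sample (ddof = 1) standard
deviation are computed on the *training* genes only and applied to all
genes; applying training statistics to the held-out genes is what keeps
holdout scoring leak-free. Variables with sample variance below 1e-12 on
the training genes are dropped and recorded.

**Imputation.** Missing entries in continuous, non-excluded predictors are
filled by chained iterative imputation (scikit-learn's `IterativeImputer`,
max 10 rounds, relative tolerance 1e-4, deterministic under its seed). The
per-column regressor defaults to a Bayesian ridge: with ~170 columns of
which only a handful are relevant to any target column, nearest-neighbour
distances are dominated by noise dimensions and k-NN imputation collapses
toward the column mean, destroying a measurable slice of planted signal
(~3% of signal variance on the default synthetic study, vs ~1% for the
linear imputer). A 5-NN regressor remains available via `estimator="knn"`.
GO membership and amino-acid composition groups are excluded from
imputation (they are generated complete; in real tables the binary/
compositional structure would be distorted by regression imputation), as
are responses.

**Split.** The 30% holdout is drawn once on the primary response's gene
universe (|test| = round(0.3·n), seeded permutation) and the same held-out
genes, intersected with availability, score every additional response. The
fraction is configurable; 0.30 is the default.

## Network centrality

Two undirected, unweighted simple graphs (functional and physical) are
built from STRING-format `protein1 protein2 combined_score` edge lists,
keeping edges with score/1000 ≥ 0.400 (inclusive). Per network and protein:

- degree — neighbour count, unnormalized;
- closeness — (r−1)/Σd within the protein's connected component (r =
  component size; isolated nodes get 0). Whole-graph and harmonic variants
  were rejected because the average-distance definition is undefined for
  unreachable nodes;
- betweenness — Σ σ_st(v)/σ_st over unordered pairs, endpoints excluded,
  shortest paths counted with multiplicity;
- eigenvector — principal eigenvector of the whole-graph adjacency,
  non-negative, max entry scaled to 1. Computed by power iteration from the
  all-ones vector on A + I: the unit shift leaves eigenvectors unchanged
  but makes the leading eigenvalue strictly dominant on bipartite graphs,
  where iteration on A itself oscillates between ±λ_max. Successive-change
  tolerance 1e-12 (max 5,000 iterations) so the returned vector agrees with
  a dense eigendecomposition to well below 1e-9.

Betweenness and shortest-path distances are evaluated through igraph's C
implementation; the test suite checks all four metrics against independent
brute-force BFS/eigen oracles on random small graphs.

Genes absent from a network receive centrality 0 with a presence flag of
false (kept in the profile table, not as a predictor): absence of
interaction evidence is treated as informative, and imputing a whole
variable group that covers ~20% of genes would let the imputer dominate
those columns.

## Latent-variable regression

Both models centre X and y internally and reconstruct coefficients in the
original variable space, so predictions need only the stored training
means.

**PLS** uses classical single-response NIPALS deflation: w_a ∝ Xᵀy (unit
norm), t_a = X w_a, loading p_a = Xᵀt_a/t_aᵀt_a, response weight q_a,
deflate X ← X − t_a p_aᵀ. For one response this is exact (no inner
iteration) and score columns come out mutually orthogonal, which makes the
per-component shares of response variance SS_a = q_a²‖t_a‖²/‖y_c‖²
additive.

**PCR** takes the leading right singular vectors of centred X (orthonormal
loadings, descending variance) and regresses y on the orthogonal scores.
Components beyond numerical rank (σ < σ₁·1e-12) get q_a = 0.

**Component selection** is seeded 10-fold cross-validation (folds are
contiguous blocks of a seeded permutation) over A = 0…max_A, where A = 0 is
the intercept-only model, followed by the one-standard-error rule: the
smallest A whose pooled RMSEP is within one SE (standard deviation of the
per-fold RMSEPs at the argmin, divided by √K) of the minimum. Under a
pure-noise response the rule selects 0 modally; the pipeline then scores
the intercept-only prediction on the holdout while the importance tables
come from a one-component fit. Per fold, predictions for all component
counts are produced from a single fit (sequential deflation for PLS, one
SVD for PCR), keeping the full CV at 170 variables inexpensive. max_A
defaults to min(n−1, p, 100).

**Variable importance.** VIP_j = √(p·Σ_a SS_a w̃_ja² / Σ_a SS_a) with
normalised weights; mean VIP² = 1 holds identically. The PCR decomposition
contribution_j = Σ_a p_ja² SS_a (reported in percent) sums exactly to the
training R² because loadings are orthonormal and the SS_a are additive.
Both identities are asserted for every fitted model in the test suite.
Sign indeterminacy of components provably cancels in predictions, VIP, and
the decomposition (squares throughout), and is tested.

**Scoring.** RMSE and pseudo-R² = 1 − MSE/var(y) with the population (1/n)
variance, so ŷ = mean(y) scores exactly 0; negative values are possible
and meaningful.

## Partial correlations

For variable j with group g(j), the covariates are all variables *not* in
g(j) (and not the response): within-group covariates would absorb exactly
the shared biology the group represents. All columns are rank-transformed
(average ranks for ties); the partial correlation is the Pearson
correlation of the residuals of ranked x and ranked y after least-squares
projection on the ranked covariates plus intercept — equivalent to the
inverse-covariance definition for a single pair — with p-values from
t = r√((n−2−k)/(1−r²)) on n−2−k degrees of freedom. With no covariates
this reduces to ordinary Spearman with its t-approximation. Complete cases
are used per test and n recorded. Bonferroni correction multiplies by the
number of variables tested for that response (families are not pooled
across the two responses, which are reported as separate panels);
significance is adjusted p < 0.05.

When the table is complete, all tests sharing a covariate set (one per
group) are residualized in a single projection; with missing data the
per-variable complete-case path is used. Both paths agree exactly on
complete data (tested).

## Random-forest baseline

A 500-tree regression forest with mtry = max(1, ⌊p/3⌋), delegated to
scikit-learn (it is a comparison model, not a quantity this package
defines). Out-of-bag predictions give an OOB pseudo-R² via the same
1 − MSE/var(y) formula; holdout RMSE/variance explained are computed
exactly as for the latent models. One caveat found while testing: with
very small p the mtry = p/3 rule degenerates to single-feature splits
(p ≤ 5 ⇒ mtry = 1), which caps the forest's accuracy even on an exactly
recoverable univariate signal — worth remembering when comparing model
classes on narrow tables.

## Synthetic studies

The generator emulates the *shape* of the real problem, not its marginal
distributions: 2,576 genes (the dN-scale default) × ~170 predictors in the
named groups above, MCAR missingness (default 5%) in continuous
non-compositional columns, a preferential-attachment interaction network
over 80% of genes with integer edge scores spanning 150–999 (so the 0.400
threshold is exercised on both sides) and a physical edge set nested inside
the functional one, amino-acid rows drawn from a Dirichlet (summing to 1),
and GO membership as Bernoulli draws with factor-modulated propensities.

Planted structure: the 15 informative variables (10 expression, 5 size)
are correlated measurements of two latent drivers — each informative
column loads 0.85 on its group's driver factor — with coherent signs:
expression effects negative on the rate-like response (the expression–rate
anticorrelation) and size effects positive (longer genes, faster dN). A
degree-linked term (coupling 0.3, standardized degree on the thresholded
functional graph — i.e. exactly the predictor the pipeline observes) adds
the network-centrality effect. This block structure is deliberate: it
concentrates the signal in high-variance, mutually correlated directions,
the regime latent-variable regression exists for, and makes the planted
holdout R² a quantity a linear model of the observed predictors can
actually attain. Signals carried by idiosyncratic column noise or by
thresholded binaries are partly invisible to any linear method and would
make the planted R² an unreachable target by construction.

The noise standard deviation is solved in closed form from the realized
signal variance, σ² = var(s)·(1−R²*)/R²*, so the planted R²* (default 0.5)
is exact by construction, not tuned; `fresh_noise_r2` verifies it on a
large independent noise holdout. The second response is y⁺ = −y⁻ + η with
η scaled (default 1.65·sd(y⁻)) to give a response correlation near −0.52;
planted effects therefore flip sign between the two responses, which the
recovery metrics check. An optional quadratic expression term
(`nonlinear_strength`) creates the regime where the forest should beat the
linear latent models; it is off by default.

**What passing these tests shows — and does not.** Recovery at planted
R²* demonstrates that the pipeline's estimators, selection rule, and
bookkeeping are correct under a linear-Gaussian data-generating process
whose signal is latent-factor structured. It does not show that real
constraint data are linear, that real missingness is MCAR, or that real GO
structure behaves like independent Bernoulli columns; on real tables the
three importance views can and should disagree more than they do here.

## Problem sizes and determinism

Default test-suite scale: toy studies of 300–700 genes for pipeline tests
and the full 2,576-gene study across ten seeds for the recovery check;
these sizes keep the complete suite around a minute while leaving the
holdout estimates' sampling noise (sd ≈ 0.025 at n_test ≈ 770) small
relative to the recovery tolerances. The per-seed holdout R² of even the
true signal varies by ±0.05 across seeds at this test-set size, so
recovery of the planted R² is asserted on the mean over the ten
replicates, while variable-recall and sign recovery are asserted per seed.

Every stochastic step (generation, split, CV folds, imputation, forest)
takes an explicit seed; a run with identical configuration and seeds
reproduces byte-identical TSVs and reports (timestamps live only in the
stderr log).
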