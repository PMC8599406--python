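"""Gene x variable feature tables: loading, encoding, scaling, imputation, splitting.

The analyses downstream (latent-variable regression, partial correlations)
operate on a per-gene table of predictors organised in named variable groups
(expression, size, amino-acid composition, GO membership, chromosome, network
centrality) plus one or two constraint responses (a dN-like rate and a
phyloP-like conservation score).  This module owns that container and every
transformation applied to it before modelling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
BINARY = "binary"
CATEGORICAL = "categorical"

#: groups excluded from imputation by default: sparse binary GO membership and
#: the compositional amino-acid block, plus responses (never imputed).
DEFAULT_IMPUTE_EXCLUDE_PREFIXES = ("GO",)
DEFAULT_IMPUTE_EXCLUDE_GROUPS = ("amino_acid_composition",)

#: missing-value spellings accepted on load (case-insensitive).
NA_SPELLINGS = ["", "NA", "NaN", "na", "nan", "Na", "NAN"]

VAR_KINDS = {CONTINUOUS, BINARY, CATEGORICAL}


class FeatureTableError(ValueError):
    """Raised when a feature table violates its contract."""


@dataclass
class FeatureTable:
    """Genes x variables matrix with group/kind metadata and response vectors.

    ``values`` is indexed by gene ID; columns are predictor variables only —
    responses live in ``responses`` and never appear among predictors.
    Categorical source columns (e.g. chromosome) may be present until
    :func:`one_hot_encode` converts them to binary indicator variables.
    """

    values: pd.DataFrame
    variable_group: dict[str, str]
    variable_kind: dict[str, str]
    responses: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- container protocol -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def variable_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return len(self.values)

    def variables_in_group(self, group: str) -> list[str]:
        return [v for v in self.variable_names if self.variable_group[v] == group]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.variable_names:
            seen.setdefault(self.variable_group[v], None)
        return list(seen)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(),
            dict(self.variable_group),
            dict(self.variable_kind),
            self.responses.copy(),
        )

    def validate(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dups = sorted(set(idx[idx.duplicated()]))
            raise FeatureTableError(f"duplicate gene IDs: {dups}")
        cols = self.values.columns
        if cols.has_duplicates:
            raise FeatureTableError("duplicate variable names")
        for v in cols:
            if v not in self.variable_group:
                raise FeatureTableError(f"variable {v!r} has no group label")
            kind = self.variable_kind.get(v)
            if kind not in VAR_KINDS:
                raise FeatureTableError(f"variable {v!r} has invalid kind {kind!r}")
            if kind == BINARY:
                vals = self.values[v].dropna().unique()
                if not np.isin(vals, [0, 1]).all():
                    raise FeatureTableError(f"binary variable {v!r} has values outside {{0,1}}")
        overlap = set(cols) & set(self.responses.columns)
        if overlap:
            raise FeatureTableError(f"responses present among predictors: {sorted(overlap)}")
        if not self.responses.index.equals(idx):
            raise FeatureTableError("responses index does not match gene index")


@dataclass
class PreprocessState:
    """Centring/scaling statistics fitted on the training genes.

    ``means``/``sds`` are the per-variable training mean and sample standard
    deviation applied to every gene (train statistics applied to the test set
    so holdout scoring leaks nothing).  Variables with zero sample variance on
    the fitting subset are dropped and listed in ``dropped``.
    """

    means: dict[str, float]
    sds: dict[str, float]
    dropped: list[str]
    fit_on: list[str] = field(default_factory=list)
    imputation_seed: int | None = None
    imputation_excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = [v for v, s in self.sds.items() if not s > 0]
        if bad:
            raise FeatureTableError(f"non-positive standard deviations stored for {bad}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "means": self.means,
                    "sds": self.sds,
                    "dropped": self.dropped,
                    "n_fit_genes": len(self.fit_on),
                    "imputation_seed": self.imputation_seed,
                    "imputation_excluded": self.imputation_excluded,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


# ---------------------------------------------------------------------------
# loading / writing


def load_feature_table(
    path,
    schema: dict[str, tuple[str, str]],
    response_names: list[str],
    gene_column: str = "gene",
) -> FeatureTable:
    """Read a TSV into a :class:`FeatureTable`.

    ``schema`` maps predictor column name to ``(group, kind)`` with kind in
    {continuous, binary, categorical}.  Unparseable numeric cells (and the
    spellings '', 'NA', 'NaN', any case) become missing, never zero.  Columns
    absent from both schema and ``response_names`` are ignored.
    """
    raw = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=NA_SPELLINGS
    )
    if gene_column not in raw.columns:
        raise FeatureTableError(f"gene ID column {gene_column!r} not found")
    for r in response_names:
        if r not in raw.columns:
            raise FeatureTableError(f"response column {r!r} absent from {path}")
    genes = raw[gene_column]
    if genes.duplicated().any():
        dups = sorted(set(genes[genes.duplicated()]))
        raise FeatureTableError(f"duplicate gene IDs: {dups}")

    index = pd.Index(genes, name=gene_column)
    cols: dict[str, np.ndarray] = {}
    group: dict[str, str] = {}
    kind: dict[str, str] = {}
    for col, (g, k) in schema.items():
        if col not in raw.columns:
            raise FeatureTableError(f"schema column {col!r} absent from {path}")
        if k not in VAR_KINDS:
            raise FeatureTableError(f"schema kind {k!r} for column {col!r} invalid")
        series = raw[col]
        if k == CATEGORICAL:
            cols[col] = series.values
        else:
            cols[col] = pd.to_numeric(series, errors="coerce").astype(float).values
        group[col] = g
        kind[col] = k
    values = pd.DataFrame(cols, index=index)

    responses = pd.DataFrame(
        {r: pd.to_numeric(raw[r], errors="coerce").astype(float).values for r in response_names},
        index=index,
    )
    return FeatureTable(values, group, kind, responses)


def write_feature_table(table: FeatureTable, path, gene_column: str = "gene") -> None:
    """Write predictors + responses as a TSV that round-trips exactly.

    Floats are printed with 17 significant digits so ``load_feature_table``
    reproduces every value bit-identically; identical tables produce
    byte-identical files.
    """
    out = pd.concat([table.values, table.responses], axis=1)
    out.index.name = gene_column
    out.to_csv(path, sep="\t", float_format="%.17g", na_rep="NA")


def schema_of(table: FeatureTable) -> dict[str, tuple[str, str]]:
    """Column -> (group, kind) map describing ``table``, for reloading."""
    return {v: (table.variable_group[v], table.variable_kind[v]) for v in table.variable_names}


# ---------------------------------------------------------------------------
# encoding and scaling


def one_hot_encode(
    table: FeatureTable, columns: list[str], membership_sep: str = ";"
) -> FeatureTable:
    """Expand categorical or set-valued membership columns into 0/1 indicators.

    Each level becomes a variable ``<column>.<level>`` inheriting the source
    column's group; all levels are kept (no reference level dropped — the
    latent models downstream tolerate the collinearity).  A cell may hold a
    ``membership_sep``-separated list of levels, in which case each listed
    level is set to 1 for that gene.
    """
    out = table.copy()
    for col in columns:
        if col not in out.values.columns:
            raise FeatureTableError(f"column {col!r} not in table")
        series = out.values[col]
        memberships: list[set[str]] = []
        levels: dict[str, None] = {}
        for cell in series:
            if isinstance(cell, float) and np.isnan(cell):
                memberships.append(set())
                continue
            terms = {t.strip() for t in str(cell).split(membership_sep) if t.strip()}
            memberships.append(terms)
            for t in terms:
                levels.setdefault(t, None)
        g = out.variable_group[col]
        out.values = out.values.drop(columns=[col])
        del out.variable_group[col], out.variable_kind[col]
        for lv in sorted(levels):
            name = f"{col}.{lv}"
            if name in out.values.columns:
                raise FeatureTableError(f"one-hot level {name!r} collides with an existing variable")
            out.values[name] = np.array([1.0 if lv in m else 0.0 for m in memberships])
            out.variable_group[name] = g
            out.variable_kind[name] = BINARY
    out.validate()
    return out


def scale_aa_composition(table: FeatureTable, aa_columns: list[str]) -> FeatureTable:
    """Rescale per-gene amino-acid counts to proportions of the protein.

    After scaling, each gene's 20 amino-acid values sum to 1 (within 1e-12);
    a gene whose counts are all zero cannot be normalised and is an error.
    """
    missing = [c for c in aa_columns if c not in table.values.columns]
    if missing:
        raise FeatureTableError(f"amino-acid columns absent: {missing}")
    out = table.copy()
    block = out.values[aa_columns].to_numpy(dtype=float)
    if np.isnan(block).any():
        raise FeatureTableError("amino-acid columns contain missing values")
    if (block < 0).any():
        raise FeatureTableError("amino-acid counts must be non-negative")
    rowsum = block.sum(axis=1)
    zero = rowsum == 0
    if zero.any():
        bad = list(out.gene_ids[zero])
        raise FeatureTableError(f"all-zero amino-acid rows for genes: {bad}")
    out.values[aa_columns] = block / rowsum[:, None]
    return out


# ---------------------------------------------------------------------------
# preprocessing (centre/scale + low-variance removal)

_ZERO_VAR_TOL = 1e-12


def preprocess(table: FeatureTable, fit_on) -> tuple[FeatureTable, PreprocessState]:
    """Centre and scale every predictor using statistics from ``fit_on`` genes.

    Sample (ddof=1) mean/sd are computed on the fitting subset only and
    applied to all genes.  Variables whose sample variance on ``fit_on`` is
    below 1e-12 are dropped and recorded in the returned state.  Categorical
    columns must have been one-hot encoded first.
    """
    fit_on = list(fit_on)
    if len(fit_on) < 2:
        raise FeatureTableError("preprocess requires at least 2 genes in fit_on")
    cats = [v for v in table.variable_names if table.variable_kind[v] == CATEGORICAL]
    if cats:
        raise FeatureTableError(f"categorical columns not yet one-hot encoded: {cats}")
    out = table.copy()
    sub = out.values.loc[fit_on]
    means = sub.mean(axis=0, skipna=True)
    variances = sub.var(axis=0, ddof=1, skipna=True)
    dropped = [v for v in out.variable_names if not variances[v] > _ZERO_VAR_TOL]
    keep = [v for v in out.variable_names if v not in set(dropped)]
    sds = np.sqrt(variances[keep])
    out.values = (out.values[keep] - means[keep]) / sds
    out.variable_group = {v: out.variable_group[v] for v in keep}
    out.variable_kind = {v: out.variable_kind[v] for v in keep}
    state = PreprocessState(
        means={v: float(means[v]) for v in keep},
        sds={v: float(sds[v]) for v in keep},
        dropped=dropped,
        fit_on=fit_on,
    )
    return out, state


# ---------------------------------------------------------------------------
# imputation


def default_impute_exclusions(table: FeatureTable) -> list[str]:
    """Groups excluded from imputation: GO membership and amino-acid blocks."""
    out = []
    for g in table.groups:
        if g in DEFAULT_IMPUTE_EXCLUDE_GROUPS or g.startswith(DEFAULT_IMPUTE_EXCLUDE_PREFIXES):
            out.append(g)
    return out


def impute_missing(
    table: FeatureTable,
    exclude_groups: list[str] | None = None,
    seed: int = 0,
    max_iter: int = 10,
    estimator: str = "bayesian_ridge",
) -> FeatureTable:
    """Fill missing entries in continuous predictors by chained iterative imputation.

    Each incomplete column is modelled from the other non-excluded predictor
    columns, cycling until successive imputations change by less than 1e-4
    (relative) or ``max_iter`` rounds.  The per-column regressor is a
    Bayesian ridge by default — with ~170 mostly weakly informative
    dimensions a regularised linear fit recovers correlated-column structure
    far better than local neighbour averaging — or a 5-NN regressor with
    ``estimator="knn"``.  Excluded groups (by default GO membership and
    amino-acid composition) and the responses are never touched.  Identical
    (table, seed) gives bit-identical output.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer
    from sklearn.linear_model import BayesianRidge
    from sklearn.neighbors import KNeighborsRegressor

    if exclude_groups is None:
        exclude_groups = default_impute_exclusions(table)
    excluded = set(exclude_groups)
    out = table.copy()
    cols = [
        v
        for v in out.variable_names
        if out.variable_group[v] not in excluded and out.variable_kind[v] != CATEGORICAL
    ]
    block = out.values[cols].to_numpy(dtype=float)
    all_missing = [c for c, col in zip(cols, block.T) if np.isnan(col).all()]
    if all_missing:
        raise FeatureTableError(f"columns entirely missing, cannot impute: {all_missing}")
    targets = [
        c
        for c in cols
        if out.variable_kind[c] == CONTINUOUS and out.values[c].isna().any()
    ]
    if not targets:
        return out
    if estimator == "bayesian_ridge":
        reg = BayesianRidge()
    elif estimator == "knn":
        reg = KNeighborsRegressor(n_neighbors=5)
    else:
        raise FeatureTableError(f"unknown imputation estimator {estimator!r}")
    imputer = IterativeImputer(
        estimator=reg,
        max_iter=max_iter,
        tol=1e-4,
        random_state=seed,
        sample_posterior=False,
    )
    filled = imputer.fit_transform(block)
    for j, c in enumerate(cols):
        if c in targets:
            mask = out.values[c].isna().to_numpy()
            vals = out.values[c].to_numpy(dtype=float, copy=True)
            vals[mask] = filled[mask, j]
            out.values[c] = vals
    return out


# ---------------------------------------------------------------------------
# train/test split


def split_train_test(
    table: FeatureTable,
    test_fraction: float,
    seed: int,
    response: str | None = None,
) -> tuple[list[str], list[str]]:
    """Partition genes with a non-missing ``response`` into train/test sets.

    ``|test| = round(test_fraction * n)``; the partition is a seeded
    permutation, so the same seed always returns the same gene sets.  The
    returned test set is intended to be reused verbatim (intersected with the
    available genes) when scoring a second response.
    """
    if not 0 < test_fraction < 1:
        raise FeatureTableError("test_fraction must be in (0, 1)")
    if response is None:
        response = table.responses.columns[0]
    if response not in table.responses.columns:
        raise FeatureTableError(f"unknown response {response!r}")
    avail = table.gene_ids[table.responses[response].notna().to_numpy()]
    n = len(avail)
    if n == 0:
        raise FeatureTableError(f"no genes with non-missing response {response!r}")
    n_test = round(test_fraction * n)
    if n_test == 0 or n_test == n:
        raise FeatureTableError(
            f"test_fraction {test_fraction} leaves an empty side (n={n}, n_test={n_test})"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test = sorted(avail[perm[:n_test]])
    train = sorted(avail[perm[n_test:]])
    return train, test
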