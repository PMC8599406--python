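"""End-to-end orchestration of the constraint-determinants analysis.

Order of stages: load -> one-hot encode -> amino-acid scaling -> centrality
merge -> imputation -> train/test split -> centre/scale on the training
genes -> cross-validated component selection -> PLS and PCR fits -> holdout
scoring -> VIP and PCR variance decomposition -> grouped partial
correlations (all genes) -> random-forest baseline.  Every source of
randomness is seeded, so a config run twice yields an identical report.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, feature_table as ft, latent, network as net_mod

log = logging.getLogger("evodet")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """Inputs, defaults and seeds for one analysis run.

    Defaults follow the study settings: 30% holdout, STRING score threshold
    0.400, 10-fold CV, a 500-tree forest with mtry = p/3, and a significance
    level of 0.05 (Bonferroni-adjusted).
    """

    feature_table: str = ""
    functional_links: str = ""
    physical_links: str = ""
    schema: str = ""  # JSON: column -> [group, kind]
    response_names: list[str] = field(default_factory=lambda: ["dN", "phyloP"])
    gene_column: str = "gene"
    onehot_columns: list[str] = field(default_factory=lambda: ["chromosome"])
    aa_columns: list[str] = field(default_factory=list)
    test_fraction: float = 0.30
    min_score: float = 0.400
    id_prefix_strip: str | None = None
    n_folds: int = 10
    max_components: int = 100
    seed_split: int = 1
    seed_cv: int = 2
    seed_impute: int = 3
    seed_forest: int = 4
    n_trees: int = 500
    mtry_fraction: float = 1.0 / 3.0
    alpha: float = 0.05
    run_forest: bool = True
    impute_exclude_groups: list[str] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0,1)")
        if not self.response_names:
            raise ValueError("at least one response is required")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class AnalysisReport:
    """Everything one analysis run produced, regenerable from config + inputs."""

    metrics: dict  # response -> {"pls"/"pcr"/"rf": FitMetrics-like}
    vip: dict  # response -> pd.Series
    pct_variance: dict  # response -> pd.Series
    partial_correlations: dict  # response -> DataFrame
    selected_components: dict  # response -> {"pls": A, "pcr": A}
    gene_ids: list
    provenance: dict

    def to_dict(self) -> dict:
        out = {
            "metrics": {
                r: {m: vars(fm) for m, fm in d.items()} for r, d in self.metrics.items()
            },
            "selected_components": self.selected_components,
            "vip": {r: {k: float(v) for k, v in s.items()} for r, s in self.vip.items()},
            "pct_variance": {
                r: {k: float(v) for k, v in s.items()} for r, s in self.pct_variance.items()
            },
            "partial_correlations": {
                r: df.to_dict(orient="records") for r, df in self.partial_correlations.items()
            },
            "n_genes": len(self.gene_ids),
            "provenance": self.provenance,
        }
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def importance_table(self, response: str, table: ft.FeatureTable | None = None) -> pd.DataFrame:
        vip = self.vip[response]
        pct = self.pct_variance[response]
        df = pd.DataFrame({"variable": vip.index, "vip": vip.values})
        df["pct_variance"] = pct.reindex(vip.index).values
        if table is not None:
            df.insert(1, "group", [table.variable_group.get(v, "") for v in df["variable"]])
        return df


# ---------------------------------------------------------------------------
# random-forest baseline


def fit_rf_baseline(
    X_train,
    y_train,
    X_test,
    y_test,
    n_trees: int = 500,
    mtry_fraction: float = 1.0 / 3.0,
    seed: int = 0,
):
    """Random-forest comparison model: 500 trees, mtry = floor(p/3).

    Returns (model, holdout FitMetrics, out-of-bag pseudo-R^2).  The OOB
    pseudo-R^2 uses the same 1 - MSE/var(y) formula as the other models, on
    out-of-bag predictions over the training genes.
    """
    from sklearn.ensemble import RandomForestRegressor

    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    p = X_train.shape[1]
    if p == 0:
        raise ValueError("no predictor variables for the forest baseline")
    mtry = max(1, int(np.floor(p * mtry_fraction)))
    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X_train, y_train)
    oob = model.oob_prediction_
    oob_r2 = 1.0 - float(np.mean((y_train - oob) ** 2)) / float(np.var(y_train))
    holdout = latent.score_predictions(y_test, model.predict(X_test))
    return model, holdout, oob_r2


# ---------------------------------------------------------------------------
# orchestration


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(name, exc) from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def run_study(
    table: ft.FeatureTable,
    functional: net_mod.InteractionNetwork,
    physical: net_mod.InteractionNetwork,
    config: AnalysisConfig,
) -> AnalysisReport:
    """Run the full analysis on in-memory inputs and return the report.

    The train/test split is drawn once on the primary (first) response's
    gene universe; the same held-out genes (intersected with availability)
    score every additional response.
    """
    cfg = config
    provenance: dict = {"config": _config_echo(cfg)}

    with _stage("one_hot_encode"):
        cats = [c for c in cfg.onehot_columns if c in table.variable_names]
        table = ft.one_hot_encode(table, cats) if cats else table

    with _stage("aa_scaling"):
        aa_cols = cfg.aa_columns or table.variables_in_group("amino_acid_composition")
        if aa_cols:
            table = ft.scale_aa_composition(table, aa_cols)

    with _stage("centrality"):
        table, profile = net_mod.add_centrality_features(table, functional, physical)
        provenance["centrality_matched"] = {
            "functional": int(profile["in_functional"].sum()),
            "physical": int(profile["in_physical"].sum()),
            "genes": int(len(profile)),
        }

    with _stage("impute"):
        table = ft.impute_missing(
            table, exclude_groups=cfg.impute_exclude_groups, seed=cfg.seed_impute
        )

    with _stage("split"):
        primary = cfg.response_names[0]
        train, test = ft.split_train_test(
            table, cfg.test_fraction, cfg.seed_split, response=primary
        )

    with _stage("preprocess"):
        table_std, state = ft.preprocess(table, fit_on=train)
        provenance["dropped_variables"] = state.dropped
        provenance["n_variables"] = len(table_std.variable_names)
        provenance["n_genes"] = table_std.n_genes

    metrics: dict = {}
    vip: dict = {}
    pct: dict = {}
    pcor: dict = {}
    selected: dict = {}
    X_all = table_std.values

    for resp in cfg.response_names:
        with _stage(f"models[{resp}]"):
            avail = table_std.responses[resp].notna()
            universe = set(table_std.gene_ids[avail])
            r_test = [g for g in test if g in universe]
            r_train = [g for g in train if g in universe] + [
                g for g in sorted(universe) if g not in set(train) and g not in set(test)
            ]
            X_tr = X_all.loc[r_train]
            X_te = X_all.loc[r_test]
            y_tr = table_std.responses.loc[r_train, resp].to_numpy(dtype=float)
            y_te = table_std.responses.loc[r_test, resp].to_numpy(dtype=float)

            metrics[resp] = {}
            selected[resp] = {}
            for method, fit in (("pls", latent.fit_pls), ("pcr", latent.fit_pcr)):
                sel = latent.select_components(
                    X_tr, y_tr, max_A=cfg.max_components,
                    n_folds=cfg.n_folds, seed=cfg.seed_cv, method=method,
                )
                # A=0 means the CV curve favours the intercept-only model:
                # holdout prediction is then the training mean; the importance
                # tables still come from a one-component fit
                A = max(1, sel.selected)
                model = fit(X_tr, y_tr, A)
                if sel.selected == 0:
                    y_hat = np.full(len(y_te), float(np.mean(y_tr)))
                else:
                    y_hat = latent.predict_response(model, X_te)
                metrics[resp][method] = latent.score_predictions(y_te, y_hat)
                selected[resp][method] = {"selected": sel.selected, "fitted": A}
                if method == "pls":
                    vip[resp] = latent.vip_scores(model)
                else:
                    pct[resp] = latent.pcr_variance_decomposition(model)

        with _stage(f"partial_correlations[{resp}]"):
            pcor[resp] = association.grouped_partial_correlations(
                table_std, resp, alpha=cfg.alpha
            )

        if cfg.run_forest:
            with _stage(f"forest[{resp}]"):
                _, holdout, oob_r2 = fit_rf_baseline(
                    X_tr.to_numpy(dtype=float),
                    y_tr,
                    X_te.to_numpy(dtype=float),
                    y_te,
                    n_trees=cfg.n_trees,
                    mtry_fraction=cfg.mtry_fraction,
                    seed=cfg.seed_forest,
                )
                metrics[resp]["rf"] = holdout
                provenance.setdefault("rf_oob_pseudo_r2", {})[resp] = oob_r2

    return AnalysisReport(
        metrics=metrics,
        vip=vip,
        pct_variance=pct,
        partial_correlations=pcor,
        selected_components=selected,
        gene_ids=list(table.gene_ids),
        provenance=provenance,
    )


def _config_echo(cfg: AnalysisConfig) -> dict:
    echo = asdict(cfg)
    return {k: v for k, v in echo.items()}


def run_analysis(config: AnalysisConfig, outdir=None) -> AnalysisReport:
    """File-based entry point: load inputs per config, run, optionally write outputs."""
    with _stage("load"):
        with open(config.schema) as fh:
            raw_schema = json.load(fh)
        schema = {c: (g, k) for c, (g, k) in raw_schema.items()}
        table = ft.load_feature_table(
            config.feature_table, schema, config.response_names, gene_column=config.gene_column
        )
        functional = net_mod.load_string_edges(
            config.functional_links, config.min_score, config.id_prefix_strip, kind="functional"
        )
        physical = net_mod.load_string_edges(
            config.physical_links, config.min_score, config.id_prefix_strip, kind="physical"
        )
    report = run_study(table, functional, physical, config)
    if outdir is not None:
        write_report(report, outdir)
    return report


def write_report(report: AnalysisReport, outdir) -> None:
    """Serialize the report: JSON summary + per-response TSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.to_json(outdir / "report.json")
    for resp, df in report.partial_correlations.items():
        association.write_partial_correlations(df, outdir / f"pcor_{resp}.tsv")
    for resp in report.vip:
        imp = report.importance_table(resp)
        imp.to_csv(outdir / f"importance_{resp}.tsv", sep="\t", index=False, float_format="%.6g")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(report.provenance, fh, indent=2, sort_keys=True, default=str)


def configure_logging(level=logging.INFO) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(level)
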