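"""Fit the latent-variable models and derive both importance decompositions.

Runs the full preprocessing + modelling pipeline (one-hot encoding,
amino-acid scaling, centrality merge, imputation, 30% holdout split,
centring/scaling on the training genes, 10-fold CV component selection, PLS
and PCR fits) on the study from 01_simulate.py, then writes holdout metrics,
VIP scores and the PCR percent-variance table to results/.  The report is
cached under scratch/ for the downstream steps.
"""

import json
import pickle
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from evodet import AnalysisConfig, load_string_edges, run_study  # noqa: E402
from evodet.feature_table import load_feature_table  # noqa: E402

STUDY_DIR = ROOT / "scratch" / "synthetic_study"
RESULTS = ROOT / "results"


def load_study_inputs():
    with open(STUDY_DIR / "schema.json") as fh:
        schema = {c: tuple(gk) for c, gk in json.load(fh).items()}
    table = load_feature_table(STUDY_DIR / "features.tsv", schema, ["dN", "phyloP"])
    functional = load_string_edges(STUDY_DIR / "functional_links.txt", 0.400, "4896.")
    physical = load_string_edges(
        STUDY_DIR / "physical_links.txt", 0.400, "4896.", kind="physical"
    )
    return table, functional, physical


def main() -> None:
    table, functional, physical = load_study_inputs()
    config = AnalysisConfig(run_forest=False)
    report = run_study(table, functional, physical, config)

    RESULTS.mkdir(exist_ok=True)
    for resp in ("dN", "phyloP"):
        imp = report.importance_table(resp, table).sort_values("vip", ascending=False)
        imp.to_csv(RESULTS / f"03_importance_{resp}.tsv", sep="\t",
                   index=False, float_format="%.6g")
    metrics = {
        resp: {m: vars(fm) for m, fm in d.items()} for resp, d in report.metrics.items()
    }
    metrics["selected_components"] = report.selected_components
    with open(RESULTS / "03_model_metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    with open(ROOT / "scratch" / "report.pkl", "wb") as fh:
        pickle.dump(report, fh)

    for resp in ("dN", "phyloP"):
        pls, pcr = report.metrics[resp]["pls"], report.metrics[resp]["pcr"]
        print(f"{resp}: PLS {100 * pls.variance_explained:.1f}% "
              f"(A={report.selected_components[resp]['pls']['fitted']}), "
              f"PCR {100 * pcr.variance_explained:.1f}% "
              f"(A={report.selected_components[resp]['pcr']['fitted']}) "
              f"of holdout variance explained")
        top = report.vip[resp].sort_values(ascending=False).head(3)
        print(f"  top VIP: " + ", ".join(f"{v}={s:.2f}" for v, s in top.items()))


if __name__ == "__main__":
    main()
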