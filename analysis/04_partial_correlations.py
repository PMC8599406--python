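"""Grouped Spearman partial correlations of every variable with constraint.

Reuses the preprocessed report from 03_fit_models.py and writes the
Bonferroni-adjusted partial-correlation panels for the dN-like and
phyloP-like responses, highlighting the significant associations and the
expected sign flip between the two response conventions.
"""

import pickle
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from evodet.association import write_partial_correlations  # noqa: E402

RESULTS = ROOT / "results"


def main() -> None:
    with open(ROOT / "scratch" / "report.pkl", "rb") as fh:
        report = pickle.load(fh)

    for resp in ("dN", "phyloP"):
        df = report.partial_correlations[resp]
        write_partial_correlations(df, RESULTS / f"04_pcor_{resp}.tsv")
        sig = df[df["significant"]].sort_values("rho")
        print(f"{resp}: {len(sig)}/{len(df)} variables significant "
              f"(Bonferroni-adjusted p < 0.05)")
        if len(sig):
            strongest = sig.iloc[0] if abs(sig.iloc[0]["rho"]) > abs(sig.iloc[-1]["rho"]) \
                else sig.iloc[-1]
            print(f"  strongest: {strongest['variable']} rho={strongest['rho']:.3f}")

    dn = report.partial_correlations["dN"].set_index("variable")["rho"]
    pp = report.partial_correlations["phyloP"].set_index("variable")["rho"]
    sig_dn = report.partial_correlations["dN"].set_index("variable")["significant"]
    both = sig_dn[sig_dn].index
    flipped = sum((dn[v] * pp[v]) < 0 for v in both)
    print(f"sign flip dN vs phyloP among dN-significant variables: {flipped}/{len(both)}")


if __name__ == "__main__":
    main()
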