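"""Report the treatment-signature PCA from the fitted pipeline.

Reads the score/loading tables written by 03_fit_conditions.py and
prints the explained variance and the top-loading receptor x parameter
variables for the leading component, for both matrix modes (posterior
mean parameters; predicted lysate fold changes).
"""

import json
from pathlib import Path

import pandas as pd

IN = Path("results/pipeline")


def main() -> None:
    manifest = json.loads((IN / "run_manifest.json").read_text())
    for mode in ("param_means", "fold_change"):
        evr = manifest["pca"][mode]["explained_variance_ratio"]
        loadings = pd.read_csv(IN / f"pca_{mode}_loadings.csv", index_col=0)
        top = loadings["PC1"].abs().sort_values(ascending=False).head(3)
        print(f"mode {mode}: PC1 explains {100 * evr[0]:.1f}% of variance")
        for var in top.index:
            print(f"  PC1 loading {loadings.loc[var, 'PC1']:+.3f}  {var}")


if __name__ == "__main__":
    main()
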