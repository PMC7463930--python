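#!/usr/bin/env python
"""PCA of the study set: scores, correlation circle, central group hulls.

Projects peptides onto the leading principal components of the standardized
ACC space, writes per-variable correlations with each PC, and the convex
areas containing the 50% most central peptides of each group in the PC1/PC2
plane.
"""

import json
from pathlib import Path

import pandas as pd

from peptraits import ordination as ord_

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = pd.read_csv(ROOT / "acc_standardized.tsv", sep="\t", index_col=0)
    groups = table.pop("group")

    result = ord_.pca(table, ncomp=3)
    result.scores.join(groups).to_csv(ROOT / "pca_scores.tsv", sep="\t", float_format="%.10g")
    result.loadings.to_csv(ROOT / "pca_loadings.tsv", sep="\t", float_format="%.10g")
    circle = ord_.correlation_circle(table, result)
    circle.to_csv(ROOT / "correlation_circle.tsv", sep="\t", float_format="%.10g")

    hulls = ord_.group_hulls(result.scores[["PC1", "PC2"]], groups, fraction=0.5)
    with open(ROOT / "group_hulls.json", "w") as fh:
        json.dump({g: v.tolist() for g, v in hulls.items()}, fh, indent=2)

    evr = result.explained_variance_ratio
    print("explained variance: " + ", ".join(f"{k} {v:.1%}" for k, v in evr.items()))
    top = circle["PC1"].abs().nlargest(3)
    print("descriptors most correlated with PC1: " + ", ".join(top.index))
    print(f"central 50% hulls written for groups: {sorted(hulls)}")


if __name__ == "__main__":
    main()
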