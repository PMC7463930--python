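#!/usr/bin/env python
"""K-means clustering of the study set with silhouette selection of k.

Expects 02_featurize.py to have written results/acc_standardized.tsv.
Reports the selected k, the per-k silhouette profile, and a chi-square test
of whether cluster membership is independent of functional group.
"""

import json
from pathlib import Path

import pandas as pd

from peptraits import clustering as cl

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    table = pd.read_csv(ROOT / "acc_standardized.tsv", sep="\t", index_col=0)
    groups = table.pop("group")
    model, silhouettes = cl.select_k(table, kmin=2, kmax=10, n_init=100, seed=SEED)

    model.labels.to_csv(ROOT / "cluster_labels.tsv", sep="\t")
    contingency = cl.composition_table(model.labels, groups)
    chi2, dof, p, _ = cl.composition_test(model.labels, groups)
    contingency.to_csv(ROOT / "cluster_contingency.tsv", sep="\t")
    with open(ROOT / "clustering.json", "w") as fh:
        json.dump(
            {
                "k": model.k,
                "mean_silhouette": model.mean_silhouette,
                "silhouette_by_k": {int(k): float(v) for k, v in silhouettes.items()},
                "chi2": {"statistic": chi2, "dof": dof, "p": p},
                "seed": SEED,
            },
            fh,
            indent=2,
        )

    print("silhouette by k:")
    print(silhouettes.to_string(float_format="%.3f"))
    print(f"\nselected k = {model.k} (best mean silhouette {model.mean_silhouette:.3f})")
    print("\ncluster x group contingency:")
    print(contingency.to_string())
    print(f"\nchi2 = {chi2:.1f}, dof = {dof}, p = {p:.3g}")
    print("-> cluster membership tracks functional group" if p < 0.05 else "-> no association")


if __name__ == "__main__":
    main()
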