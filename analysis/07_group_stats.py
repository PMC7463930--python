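#!/usr/bin/env python
"""Group-wise feature distributions and pairwise Wilcoxon tests.

Summarises the physico-chemical features per functional group and tests all
pairwise group differences with Holm-corrected two-sided rank-sum tests.
Peptides without a detected helix contribute no value to helix features.
"""

from pathlib import Path

import pandas as pd

from peptraits import group_stats as gs

ROOT = Path(__file__).resolve().parent.parent / "results"

FEATURES = ["max_hydrophobicity", "net_charge", "helix_len", "helix_net_charge", "helix_fraction"]


def main() -> None:
    feats = pd.read_csv(ROOT / "physchem_features.tsv", sep="\t", index_col=0)
    groups = feats.pop("group")
    feats = feats[FEATURES]

    summary = gs.summarize(feats, groups)
    summary.to_csv(ROOT / "feature_summary.tsv", sep="\t", index=False, float_format="%.6g")

    tests = gs.feature_tests(feats, groups)
    for feature, mat in tests.items():
        mat.to_csv(ROOT / f"wilcoxon_{feature}.tsv", sep="\t", float_format="%.6g")

    print(summary.pivot(index="feature", columns="group", values="median").to_string(float_format="%.2f"))
    print("\npairwise Holm-adjusted Wilcoxon p-values (net_charge):")
    print(tests["net_charge"].to_string(float_format="%.3g"))
    sig = {
        f: int((m.stack() < gs.ALPHA).sum() // 2) for f, m in tests.items()
    }
    print("\nsignificant pairs per feature (p < 0.05):", sig)


if __name__ == "__main__":
    main()
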