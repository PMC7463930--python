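#!/usr/bin/env python
"""Compute ACC descriptors and physico-chemical features for the study set.

Reads results/data/study.fasta, writes ACC tables (raw and standardized) and
the per-peptide feature table (hydrophobicity, net charge, amphiphilic helix)
under results/.
"""

from pathlib import Path

import pandas as pd

from peptraits import descriptors as dsc
from peptraits import peptide_io as pio
from peptraits import physchem as pc

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    peptides = pio.read_fasta(ROOT / "data" / "study.fasta")
    peptides, _ = pio.attach_groups(peptides, pio.read_group_table(ROOT / "data" / "study_labels.tsv"))
    peptides = pio.curate(peptides)
    groups = pd.Series({p.id: p.group.major for p in peptides}, name="group")

    acc = dsc.acc_table(peptides)
    std, means, scales = dsc.standardize(acc)
    acc.join(groups).to_csv(ROOT / "acc_raw.tsv", sep="\t", float_format="%.10g")
    std.join(groups).to_csv(ROOT / "acc_standardized.tsv", sep="\t", float_format="%.10g")

    feats = pc.feature_table(peptides)
    feats.join(groups).to_csv(ROOT / "physchem_features.tsv", sep="\t", float_format="%.10g")

    with_helix = feats["helix_len"].notna()
    print(f"{len(peptides)} peptides -> 36 ACC terms each")
    print(f"amphiphilic helix detected in {int(with_helix.sum())}/{len(peptides)} peptides")
    by_group = feats.join(groups).groupby("group")["helix_fraction"].mean()
    print("mean helix fraction by group:")
    print(by_group.to_string(float_format="%.2f"))


if __name__ == "__main__":
    main()
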