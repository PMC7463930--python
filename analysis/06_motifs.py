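#!/usr/bin/env python
"""Scan the study set for FGLK-type and Hsp70-binding composition motifs.

Uses the packaged heuristic rules (10-residue FGLK window requiring aromatic,
helix-breaking, small-hydrophobic and basic residues; hydrophobic-rich 7-mer
within the first 10 residues for Hsp70). Counts are rule-dependent and are
reported per functional group.
"""

from pathlib import Path

import pandas as pd

from peptraits import motifs as mt
from peptraits import peptide_io as pio

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    peptides = pio.read_fasta(ROOT / "data" / "study.fasta")
    peptides, _ = pio.attach_groups(
        peptides, pio.read_group_table(ROOT / "data" / "study_labels.tsv")
    )
    peptides = pio.curate(peptides)
    groups = pd.Series({p.id: p.group.major for p in peptides}, name="group")

    rules = [mt.FGLK_DEFAULT, mt.HSP70_DEFAULT]
    counts = mt.count_motifs(peptides, rules)
    counts.to_csv(ROOT / "motif_counts.tsv", sep="\t")
    mt.hits_table(peptides, rules).to_csv(ROOT / "motif_hits.tsv", sep="\t", index=False)

    summary = counts.join(groups).groupby("group").agg(["mean", lambda s: (s > 0).mean()])
    print("motif prevalence by group (mean count / fraction of peptides with >=1 hit):")
    print(summary.to_string(float_format="%.2f"))


if __name__ == "__main__":
    main()
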