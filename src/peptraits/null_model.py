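"""Helix-charge statistics of the random-peptide null model.

Random peptides drawn from background amino-acid frequencies with
targeting-peptide-like lengths are scanned for amphiphilic helices; the
helices found this way differ qualitatively from those of targeting and
antimicrobial peptides: only about half are positively charged, and the
positively charged ones often still contain several acidic residues, whereas
targeting-peptide helices are overwhelmingly cationic and acid-free.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import physchem, synthetic_data


@dataclass(frozen=True)
class NullHelixStats:
    """Charge composition of amphiphilic helices detected in random peptides."""

    n_peptides: int
    n_detected: int
    n_positive: int
    n_positive_with_many_acidic: int  # positive helices with > 2 D/E residues

    @property
    def pct_positive(self) -> float:
        """Percent of detected helices with net charge > 0."""
        return 100.0 * self.n_positive / self.n_detected if self.n_detected else float("nan")

    @property
    def pct_positive_many_acidic(self) -> float:
        """Percent of positive helices containing more than two D/E residues."""
        return (
            100.0 * self.n_positive_with_many_acidic / self.n_positive
            if self.n_positive
            else float("nan")
        )


def helix_charge_stats(
    n: int = 200,
    seed: int = 0,
    criterion: physchem.HelixCriterion = physchem.HelixCriterion(),
    lengths: synthetic_data.LengthModel = synthetic_data.LengthModel(),
) -> NullHelixStats:
    """Generate ``n`` random peptides, detect helices, summarise their charges."""
    peptides = synthetic_data.random_peptides(n, lengths=lengths, seed=seed)
    scale = physchem.load_hydrophobicity()
    detected = positive = many_acidic = 0
    for p in peptides:
        helix = physchem.find_amphiphilic_helix(p, scale, criterion)
        if helix is None:
            continue
        detected += 1
        if helix.net_charge > 0:
            positive += 1
            segment = p.sequence[helix.start : helix.end]
            if sum(aa in "DE" for aa in segment) > 2:
                many_acidic += 1
    return NullHelixStats(n, detected, positive, many_acidic)
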