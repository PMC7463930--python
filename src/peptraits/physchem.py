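"""Per-peptide physico-chemical features.

Implements the feature set used to compare targeting peptides with helical
amphiphilic antimicrobial peptides: maximal windowed hydrophobicity, net
charge at pH 7.4, the longest segment able to form an amphiphilic alpha-helix
(Heliquest-style helical-wheel criterion), the net charge of that segment, and
the fraction of the peptide it covers.

Hydrophobicity uses an octanol/water partitioning scale (Fauchère–Pliska).
Amphiphilicity is quantified by the Eisenberg mean hydrophobic moment: residues
are placed on a helical wheel at 100° per residue and the per-residue
hydrophobicities are summed as vectors; a large resultant means hydrophobic
residues cluster on one helix face. A window qualifies as amphiphilic when its
mean moment reaches a configurable threshold (default 0.36 on the packaged
scale). The exact wheel criterion is therefore criterion-dependent and results
should be read as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import _load_table
from .peptide_io import Peptide, PeptideError, STANDARD_AA

_POSITIVE = frozenset("KR")
_NEGATIVE = frozenset("DE")


def load_hydrophobicity(path: str | Path | None = None) -> dict[str, float]:
    """Octanol/water hydrophobicity scale; packaged Fauchère–Pliska by default."""
    if path is None:
        return {aa: v[0] for aa, v in _load_table("hydrophobicity_octanol.tsv", ("h",)).items()}
    df = pd.read_csv(path, sep="\t")
    table = {r["aa"]: float(r["h"]) for _, r in df.iterrows()}
    if set(table) != STANDARD_AA:
        raise ValueError(f"{path}: hydrophobicity table must cover the 20 standard amino acids")
    return table


@dataclass(frozen=True)
class HelixCriterion:
    """Amphiphilic-helix detection parameters.

    angle_per_residue: helical-wheel rotation per residue, degrees (100 for an
    alpha helix); min_len: shortest reportable helix (9 residues, one window of
    the hydrophobicity scan and ~2.5 helix turns); moment_threshold: minimal
    mean hydrophobic moment for a window to count as amphiphilic.
    """

    angle_per_residue: float = 100.0
    min_len: int = 9
    moment_threshold: float = 0.36

    def __post_init__(self) -> None:
        if not 0 < self.angle_per_residue < 360:
            raise ValueError("angle_per_residue must be in (0, 360)")
        if self.min_len < 2:
            raise ValueError("min_len must be >= 2")


@dataclass(frozen=True)
class AmphiphilicHelix:
    """Longest amphiphilic segment of a peptide (0-based half-open indices)."""

    start: int
    end: int
    mean_moment: float
    net_charge: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def report_coords(self) -> tuple[int, int]:
        """1-based inclusive coordinates for reports."""
        return self.start + 1, self.end


def max_window_hydrophobicity(
    peptide: Peptide, scale: dict[str, float] | None = None, window: int = 9
) -> float:
    """Highest mean hydrophobicity over all sliding windows of ``window`` residues."""
    if scale is None:
        scale = load_hydrophobicity()
    h = np.array([scale[aa] for aa in peptide.sequence])
    if h.size < window:
        raise PeptideError(
            f"peptide {peptide.id!r}: length {h.size} < window {window}"
        )
    csum = np.concatenate([[0.0], np.cumsum(h)])
    return float(np.max((csum[window:] - csum[:-window]) / window))


def net_charge(sequence: str) -> int:
    """Net charge at pH 7.4: (#K + #R) − (#D + #E); His and termini neutral."""
    return sum(aa in _POSITIVE for aa in sequence) - sum(aa in _NEGATIVE for aa in sequence)


def mean_hydrophobic_moment(
    segment: str,
    scale: dict[str, float] | None = None,
    angle_per_residue: float = 100.0,
) -> float:
    """Eisenberg mean hydrophobic moment of a segment on a helical wheel.

    ||sum_n h_n (cos nδ, sin nδ)|| / m for a segment of m residues at wheel
    angle δ per residue. Depends on the raw hydrophobicity values (it is not
    invariant to adding a constant to the scale).
    """
    if len(segment) < 2:
        raise PeptideError("hydrophobic moment needs a segment of >= 2 residues")
    if scale is None:
        scale = load_hydrophobicity()
    h = np.array([scale[aa] for aa in segment])
    delta = math.radians(angle_per_residue)
    angles = delta * np.arange(len(segment))
    mx = h @ np.cos(angles)
    my = h @ np.sin(angles)
    return float(math.hypot(mx, my) / len(segment))


def find_amphiphilic_helix(
    peptide: Peptide,
    scale: dict[str, float] | None = None,
    criterion: HelixCriterion = HelixCriterion(),
) -> AmphiphilicHelix | None:
    """Longest contiguous segment that can form an amphiphilic helix, or None.

    Scans every window of length >= ``criterion.min_len`` (exhaustive O(N² m);
    peptides are <= 100 residues so this is cheap), keeps windows whose mean
    hydrophobic moment reaches the threshold, and returns the longest; ties go
    to the most N-terminal window. The helix net charge is the net charge of
    the returned segment.
    """
    if scale is None:
        scale = load_hydrophobicity()
    seq = peptide.sequence
    n = len(seq)
    if n < criterion.min_len:
        return None
    h = np.array([scale[aa] for aa in seq])
    delta = math.radians(criterion.angle_per_residue)
    angles = delta * np.arange(n)
    hx, hy = h * np.cos(angles), h * np.sin(angles)
    cx = np.concatenate([[0.0], np.cumsum(hx)])
    cy = np.concatenate([[0.0], np.cumsum(hy)])
    best: AmphiphilicHelix | None = None
    # longest first, most N-terminal first within a length
    for length in range(n, criterion.min_len - 1, -1):
        for start in range(0, n - length + 1):
            end = start + length
            # wheel phase is relative to the window start; rotating all vectors
            # by a fixed angle leaves the resultant magnitude unchanged, so the
            # prefix sums in the peptide frame give the same moment
            mx = cx[end] - cx[start]
            my = cy[end] - cy[start]
            moment = math.hypot(mx, my) / length
            if moment >= criterion.moment_threshold:
                seg = seq[start:end]
                return AmphiphilicHelix(start, end, moment, net_charge(seg))
    return best


def amphiphilic_fraction(peptide: Peptide, helix: AmphiphilicHelix | None) -> float:
    """Fraction of the peptide covered by its amphiphilic helix; 0 if none."""
    if helix is None:
        return 0.0
    if helix.end > len(peptide):
        raise PeptideError("helix does not fit the peptide it is reported for")
    return helix.length / len(peptide)


def feature_table(
    peptides,
    scale: dict[str, float] | None = None,
    criterion: HelixCriterion = HelixCriterion(),
    window: int = 9,
) -> pd.DataFrame:
    """All physico-chemical features for a peptide collection.

    Helix columns are NaN (or 0 for ``helix_fraction``) for peptides with no
    detected amphiphilic helix. Coordinates are 1-based inclusive.
    """
    if scale is None:
        scale = load_hydrophobicity()
    rows = []
    for p in peptides:
        helix = find_amphiphilic_helix(p, scale, criterion)
        row = {
            "id": p.id,
            "length": len(p),
            "max_hydrophobicity": (
                max_window_hydrophobicity(p, scale, window) if len(p) >= window else np.nan
            ),
            "net_charge": net_charge(p.sequence),
            "helix_start": np.nan,
            "helix_end": np.nan,
            "helix_len": np.nan,
            "helix_net_charge": np.nan,
            "helix_fraction": 0.0,
            "helix_moment": np.nan,
        }
        if helix is not None:
            s, e = helix.report_coords()
            row.update(
                helix_start=s,
                helix_end=e,
                helix_len=helix.length,
                helix_net_charge=helix.net_charge,
                helix_fraction=amphiphilic_fraction(p, helix),
                helix_moment=helix.mean_moment,
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")
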