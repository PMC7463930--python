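"""Peptide containers, FASTA/label-table IO, and length curation.

Peptides are short (tens of residues) N-terminal targeting or antimicrobial
sequences over the 20 standard amino acids. Group labels (mTP, cTP, eSP, ...)
live in a sidecar TSV rather than in FASTA headers, keeping the FASTA standard;
a ``header_labels`` flag accepts ``id|major|minor``-encoded headers instead.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Allowed major group labels.
MAJOR_GROUPS = frozenset({"TP", "SP", "HA-RAMP", "globular-AMP", "random"})

#: Minor labels with a fixed major; HA-RAMP family names and species are free-form.
_MINOR_TO_MAJOR = {
    "mTP": "TP",
    "cTP": "TP",
    "eSP": "SP",
    "bSP": "SP",
    "tSP": "SP",
}


class PeptideError(ValueError):
    """Raised on malformed sequence input or inconsistent labels."""


@dataclass(frozen=True)
class GroupLabel:
    """Functional group of a peptide: a major class and an optional sub-label."""

    major: str
    minor: str | None = None

    def __post_init__(self) -> None:
        if self.major not in MAJOR_GROUPS:
            raise PeptideError(
                f"unknown major group {self.major!r}; expected one of {sorted(MAJOR_GROUPS)}"
            )
        if self.minor is not None:
            expected = _MINOR_TO_MAJOR.get(self.minor)
            if expected is not None and expected != self.major:
                raise PeptideError(
                    f"minor label {self.minor!r} belongs under {expected!r}, not {self.major!r}"
                )


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with identity, optional group label, and provenance."""

    id: str
    sequence: str
    group: GroupLabel | None = None
    source: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise PeptideError(f"peptide {self.id!r}: empty sequence")
        bad = sorted(set(seq) - STANDARD_AA)
        if bad:
            raise PeptideError(
                f"peptide {self.id!r}: non-standard residue(s) {''.join(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _check_unique_ids(peptides: Sequence[Peptide]) -> None:
    dupes = [i for i, c in Counter(p.id for p in peptides).items() if c > 1]
    if dupes:
        raise PeptideError(f"duplicate peptide id(s): {dupes}")


def read_fasta(
    path: str | Path,
    *,
    drop_invalid: bool = False,
    header_labels: bool = False,
) -> list[Peptide]:
    """Read peptides from a FASTA file.

    Records containing residues outside the 20-letter alphabet raise
    :class:`PeptideError` naming the record; with ``drop_invalid`` they are
    logged and excluded instead. With ``header_labels``, headers of the form
    ``id|major`` or ``id|major|minor`` carry the group label.
    """
    path = Path(path)
    peptides: list[Peptide] = []
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        group = None
        if header_labels and "|" in name:
            parts = name.split("|")
            name = parts[0]
            group = GroupLabel(parts[1], parts[2] if len(parts) > 2 else None)
        try:
            peptides.append(
                Peptide(name, str(record.seq), group=group, source=str(path))
            )
        except PeptideError:
            if not drop_invalid:
                raise
            logger.warning("dropping invalid record %r from %s", record.id, path)
    _check_unique_ids(peptides)
    return peptides


def write_fasta(peptides: Iterable[Peptide], path: str | Path) -> None:
    """Write peptides as FASTA (sequence only; labels go in the sidecar TSV)."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in peptides
    ]
    SeqIO.write(records, str(path), "fasta")


def read_group_table(path: str | Path) -> dict[str, GroupLabel]:
    """Read a label table TSV with header ``id<TAB>major<TAB>minor``."""
    table: dict[str, GroupLabel] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["id", "major"]:
            raise PeptideError(f"{path}: expected header 'id\\tmajor\\tminor'")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            pid, major = fields[0], fields[1]
            minor = fields[2] if len(fields) > 2 and fields[2] else None
            if pid in table:
                raise PeptideError(f"{path}:{ln}: duplicate id {pid!r}")
            table[pid] = GroupLabel(major, minor)
    return table


def write_group_table(peptides: Iterable[Peptide], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tmajor\tminor\n")
        for p in peptides:
            if p.group is None:
                continue
            fh.write(f"{p.id}\t{p.group.major}\t{p.group.minor or ''}\n")


def attach_groups(
    peptides: Sequence[Peptide], table: Mapping[str, GroupLabel]
) -> tuple[list[Peptide], list[str]]:
    """Attach group labels from an id → label table.

    Returns ``(labelled, unlabelled_ids)``; peptides absent from the table keep
    ``group=None`` and are reported in the second element.
    """
    _check_unique_ids(peptides)
    labelled: list[Peptide] = []
    missing: list[str] = []
    for p in peptides:
        if p.id in table:
            labelled.append(replace(p, group=table[p.id]))
        else:
            missing.append(p.id)
            labelled.append(p)
    if missing:
        logger.warning("%d peptide(s) missing from label table: %s", len(missing), missing)
    return labelled, missing


def curate(
    peptides: Sequence[Peptide], min_len: int = 12, max_len: int = 100
) -> list[Peptide]:
    """Keep peptides with ``min_len <= length <= max_len`` (defaults 12–100 aa).

    Removal counts are logged per group, mirroring the curation applied to the
    reference datasets before descriptor computation.
    """
    kept = [p for p in peptides if min_len <= len(p) <= max_len]
    removed = Counter(
        (p.group.major if p.group else "unlabelled")
        for p in peptides
        if not (min_len <= len(p) <= max_len)
    )
    for grp, n in sorted(removed.items()):
        logger.info("curate: removed %d peptide(s) from group %s", n, grp)
    return kept
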