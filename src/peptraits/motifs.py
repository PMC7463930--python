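"""Rule-driven scanning for chloroplast-import sequence motifs.

Chloroplast transit peptides carry loosely defined composition motifs:
FGLK-type sites — windows combining aromatic (F), helix-breaking (G), small
hydrophobic (L) and basic (K) residues, implicated in TOC receptor
interaction — and Hsp70 binding sites near the N-terminus. Neither motif has
a single canonical regular expression; here a motif is a window-composition
rule: a window length, named residue classes, and a minimum (and optionally
maximum) count per class that every reported window must satisfy.

The packaged default rules are explicit heuristics: they encode the published
glosses of both motifs, not any specific published scoring scheme, and counts
obtained with them should not be compared against counts produced by other
rule sets. Users can supply their own rules as YAML to encode a published rule
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .peptide_io import Peptide, STANDARD_AA


@dataclass(frozen=True)
class MotifRule:
    """A window-composition motif rule.

    ``requirement`` maps class name -> minimum count in the window;
    ``maximum`` maps class name -> maximum allowed count (absent = unbounded).
    ``search_region`` restricts scanning to sequence positions [start, end)
    relative to the N-terminus; ``None`` scans the whole sequence.
    """

    name: str
    window_length: int
    residue_classes: dict[str, frozenset[str]]
    requirement: dict[str, int]
    maximum: dict[str, int] = field(default_factory=dict)
    search_region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for cname, members in self.residue_classes.items():
            bad = set(members) - STANDARD_AA
            if bad:
                raise ValueError(f"rule {self.name!r}: class {cname!r} has non-standard {bad}")
        for cname in list(self.requirement) + list(self.maximum):
            if cname not in self.residue_classes:
                raise ValueError(f"rule {self.name!r}: unknown class {cname!r} in constraints")
        if self.window_length < 1:
            raise ValueError("window_length must be positive")


@dataclass(frozen=True)
class MotifHit:
    """A matched window; coordinates 1-based inclusive in reports."""

    rule: str
    start: int  # 0-based
    end: int  # 0-based exclusive
    matched: dict[str, int] = field(default_factory=dict)

    def report_coords(self) -> tuple[int, int]:
        return self.start + 1, self.end


#: Heuristic FGLK-type rule: 10-residue window with at least one residue of
#: each of the four composition classes, scanned over the whole peptide.
FGLK_DEFAULT = MotifRule(
    name="FGLK",
    window_length=10,
    residue_classes={
        "aromatic": frozenset("FWY"),
        "helix_breaking": frozenset("GP"),
        "small_hydrophobic": frozenset("LVIA"),
        "basic": frozenset("KR"),
    },
    requirement={"aromatic": 1, "helix_breaking": 1, "small_hydrophobic": 1, "basic": 1},
)

#: Heuristic Hsp70-binding rule: hydrophobic-rich 7-mer within the first 10
#: residues, with at most one acidic residue.
HSP70_DEFAULT = MotifRule(
    name="Hsp70",
    window_length=7,
    residue_classes={
        "hydrophobic": frozenset("LIVFM"),
        "acidic": frozenset("DE"),
    },
    requirement={"hydrophobic": 4},
    maximum={"acidic": 1},
    search_region=(0, 10),
)


def load_rules(path: str | Path) -> list[MotifRule]:
    """Load motif rules from a YAML file (list of rule mappings)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    rules = []
    for entry in raw:
        region = entry.get("search_region")
        rules.append(
            MotifRule(
                name=entry["name"],
                window_length=int(entry["window_length"]),
                residue_classes={
                    k: frozenset(v) for k, v in entry["residue_classes"].items()
                },
                requirement={k: int(v) for k, v in entry.get("requirement", {}).items()},
                maximum={k: int(v) for k, v in entry.get("maximum", {}).items()},
                search_region=tuple(region) if region else None,
            )
        )
    return rules


def _window_ok(window: str, rule: MotifRule) -> dict[str, int] | None:
    counts = {
        cname: sum(aa in members for aa in window)
        for cname, members in rule.residue_classes.items()
    }
    for cname, need in rule.requirement.items():
        if counts[cname] < need:
            return None
    for cname, cap in rule.maximum.items():
        if counts[cname] > cap:
            return None
    return counts


def scan(peptide: Peptide, rule: MotifRule) -> list[MotifHit]:
    """All qualifying windows for a rule, with near-duplicates merged.

    Every window of ``rule.window_length`` inside the search region that meets
    the class-count constraints qualifies; runs of windows shifted by one
    position (sharing window−1 residues) are merged into a single hit spanning
    their union, so a motif embedded in a permissive context counts once.
    A rule window longer than the sequence yields no hits (not an error).
    """
    seq = peptide.sequence
    lo, hi = rule.search_region if rule.search_region else (0, len(seq))
    hi = min(hi, len(seq))
    w = rule.window_length
    starts = []
    counts_at: dict[int, dict[str, int]] = {}
    for s in range(lo, hi - w + 1):
        counts = _window_ok(seq[s : s + w], rule)
        if counts is not None:
            starts.append(s)
            counts_at[s] = counts
    hits: list[MotifHit] = []
    for s in starts:
        if hits and s == hits[-1].end - w + 1:  # overlaps previous by w−1
            prev = hits[-1]
            hits[-1] = MotifHit(rule.name, prev.start, s + w, prev.matched)
        else:
            hits.append(MotifHit(rule.name, s, s + w, counts_at[s]))
    return hits


def count_motifs(peptides, rules: list[MotifRule]) -> pd.DataFrame:
    """Merged hit counts per peptide × rule."""
    data = {
        rule.name: [len(scan(p, rule)) for p in peptides] for rule in rules
    }
    return pd.DataFrame(data, index=[p.id for p in peptides], dtype=int)


def hits_table(peptides, rules: list[MotifRule]) -> pd.DataFrame:
    """All hits as a flat table with 1-based inclusive coordinates."""
    rows = []
    for p in peptides:
        for rule in rules:
            for h in scan(p, rule):
                s, e = h.report_coords()
                rows.append({"id": p.id, "rule": h.rule, "start": s, "end": e})
    return pd.DataFrame(rows, columns=["id", "rule", "start", "end"])
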