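"""Synthetic peptide generators: the random-peptide null model and controls.

Provides every input needed to exercise the pipeline without external
databases:

* ``random_peptides`` — the null model: residues drawn i.i.d. from background
  amino-acid frequencies (packaged UniProtKB/Swiss-Prot composition by
  default) with lengths following the targeting-peptide length distribution,
  a normal(45, 15) truncated to the curated range 12–100 aa.
* ``designed_amphiphilic`` — a positive control: leucines placed so their
  helical-wheel angles fall on one face, lysines/glycines/serines on the
  other, guaranteeing a detectable amphiphilic helix of known net charge.
* ``scramble`` — a negative control: a uniform random permutation of a
  peptide's residues, preserving composition (and hence net charge) while
  destroying the periodic face structure.
* ``two_class_dataset`` — ground truth for clustering: peptides drawn from
  two different composition profiles, labelled by profile.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .descriptors import _load_table
from .peptide_io import GroupLabel, Peptide, STANDARD_AA

_AA_ORDER = sorted(STANDARD_AA)


def load_background_frequencies(path=None) -> dict[str, float]:
    """Background amino-acid composition (packaged Swiss-Prot-style table)."""
    table = {aa: v[0] for aa, v in _load_table("uniprot_frequencies.tsv", ("freq",)).items()}
    total = sum(table.values())
    return {aa: f / total for aa, f in table.items()}


def _validate_profile(profile: dict[str, float]) -> np.ndarray:
    if set(profile) != STANDARD_AA:
        raise ValueError("composition profile must cover exactly the 20 standard amino acids")
    p = np.array([profile[aa] for aa in _AA_ORDER], dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("profile probabilities must be >= 0 and sum to 1")
    return p


@dataclass(frozen=True)
class LengthModel:
    """Peptide length distribution on the curated range [12, 100].

    Either a truncated normal (``mean``, ``sd``) rounded to integers, or an
    empirical sample (``resample``) drawn from with replacement. Defaults to
    normal(45, 15): 45 residues is the mean targeting-peptide length and the
    spread covers the short antimicrobial to long plant-TP range.
    """

    mean: float = 45.0
    sd: float = 15.0
    lo: int = 12
    hi: int = 100
    resample: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.resample is not None:
            if any(not (self.lo <= x <= self.hi) for x in self.resample):
                raise ValueError("empirical lengths must lie within [lo, hi]")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.resample is not None:
            return rng.choice(np.array(self.resample), size=n, replace=True)
        out = np.empty(n, dtype=int)
        filled = 0
        while filled < n:  # rejection sampling; acceptance is high on [12,100]
            draw = np.rint(rng.normal(self.mean, self.sd, size=2 * (n - filled)))
            ok = draw[(draw >= self.lo) & (draw <= self.hi)].astype(int)
            take = min(len(ok), n - filled)
            out[filled : filled + take] = ok[:take]
            filled += take
        return out


def random_peptides(
    n: int,
    profile: dict[str, float] | None = None,
    lengths: LengthModel = LengthModel(),
    seed: int = 0,
    prefix: str = "rand",
) -> list[Peptide]:
    """Generate ``n`` random peptides under the background-composition null model."""
    p = _validate_profile(profile or load_background_frequencies())
    rng = np.random.default_rng(seed)
    sizes = lengths.draw(n, rng)
    peptides = []
    for k, size in enumerate(sizes):
        seq = "".join(rng.choice(_AA_ORDER, size=size, p=p))
        peptides.append(
            Peptide(
                f"{prefix}_{k:04d}",
                seq,
                group=GroupLabel("random"),
                source=f"random_peptides(seed={seed})",
            )
        )
    return peptides


def designed_amphiphilic(
    length: int, n_basic: int, seed: int = 0, name: str = "design"
) -> Peptide:
    """A designed amphiphilic cationic peptide.

    Positions whose helical-wheel angle (100°/residue) falls within a 180°
    arc form the hydrophobic face and alternate methionine and alanine —
    moderate-magnitude hydrophobics, so the face is amphiphilic in place but
    random permutations of the same composition rarely are. The remaining
    (polar) positions get ``n_basic`` lysines, placed at the wheel angles
    closest to the direction opposite the face centre (which maximises the
    designed moment), and glycine/serine filler. The construction is fully
    deterministic; ``seed`` is accepted for interface symmetry with the other
    generators. Net charge equals ``n_basic`` and the default helix criterion
    detects the design down to the 9-residue minimum.
    """
    if length < 9:
        raise ValueError("designed peptides must be at least 9 residues")
    angles = [(i * 100.0) % 360.0 for i in range(length)]
    face = [i for i in range(length) if angles[i] < 180.0]
    polar = [i for i in range(length) if angles[i] >= 180.0]
    if n_basic > len(polar):
        raise ValueError(
            f"cannot place {n_basic} basic residues on a {len(polar)}-position polar face"
        )
    rad = [math.radians(angles[i]) for i in face]
    face_centre = math.degrees(
        math.atan2(sum(math.sin(a) for a in rad), sum(math.cos(a) for a in rad))
    )
    anti = (face_centre + 180.0) % 360.0

    def ang_dist(a: float, b: float) -> float:
        d = abs(a - b) % 360.0
        return min(d, 360.0 - d)

    by_anti = sorted(polar, key=lambda i: (ang_dist(angles[i], anti), i))
    basic_pos = set(by_anti[:n_basic])
    residues = []
    nface = 0
    for i in range(length):
        if i in set(face):
            residues.append("M" if nface % 2 == 0 else "A")
            nface += 1
        elif i in basic_pos:
            residues.append("K")
        else:
            residues.append("G" if i % 2 == 0 else "S")
    return Peptide(
        name, "".join(residues), group=GroupLabel("random"), source="designed_amphiphilic"
    )


def scramble(peptide: Peptide, seed: int = 0) -> Peptide:
    """Uniform random permutation of a peptide's residues (same composition)."""
    rng = np.random.default_rng(seed)
    residues = np.array(list(peptide.sequence))
    rng.shuffle(residues)
    return Peptide(
        f"{peptide.id}_scr{seed}",
        "".join(residues),
        group=peptide.group,
        source=f"scramble({peptide.id}, seed={seed})",
    )


#: Example composition profiles for clustering ground truth: one skewed toward
#: hydrophobic residues, one toward basic/polar residues.
_PROFILE_BOOST = 8.0  # strong enough contrast for unambiguous cluster truth


def hydrophobic_profile() -> dict[str, float]:
    base = load_background_frequencies()
    boost = {aa: (_PROFILE_BOOST if aa in "LIVFM" else 1.0) * base[aa] for aa in base}
    total = sum(boost.values())
    return {aa: v / total for aa, v in boost.items()}


def basic_profile() -> dict[str, float]:
    base = load_background_frequencies()
    boost = {aa: (_PROFILE_BOOST if aa in "KRSTN" else 1.0) * base[aa] for aa in base}
    total = sum(boost.values())
    return {aa: v / total for aa, v in boost.items()}


def two_class_dataset(
    n_per_class: int,
    profiles: tuple[dict[str, float], dict[str, float]] | None = None,
    lengths: LengthModel = LengthModel(),
    seed: int = 0,
) -> tuple[list[Peptide], dict[str, int]]:
    """Labelled peptides from two composition profiles (clustering ground truth).

    Returns ``(peptides, truth)`` where truth maps peptide id -> class 0/1.
    """
    if profiles is None:
        profiles = (hydrophobic_profile(), basic_profile())
    peptides: list[Peptide] = []
    truth: dict[str, int] = {}
    for cls, profile in enumerate(profiles):
        batch = random_peptides(
            n_per_class, profile, lengths, seed=seed + cls, prefix=f"class{cls}"
        )
        for p in batch:
            truth[p.id] = cls
        peptides.extend(batch)
    return peptides, truth
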