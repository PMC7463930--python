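#!/usr/bin/env python
"""Generate the synthetic study datasets.

Writes, under results/data/:
  * ``study.fasta`` + ``study_labels.tsv`` — a labelled three-group set:
    a hydrophobic-residue-rich class (stand-in for helical amphiphilic
    antimicrobial peptides), a basic-residue-rich class (stand-in for
    targeting peptides), and background-composition random peptides;
  * ``null.fasta`` — the 200-peptide random null set;
  * ``controls.fasta`` — a designed amphiphilic 18-mer and 10 scrambles.

All downstream drivers read these files, so the whole analysis is
reproducible from this script alone (seed fixed below).
"""

from pathlib import Path

from peptraits import peptide_io as pio
from peptraits import synthetic_data as sd

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    study, truth = sd.two_class_dataset(40, seed=SEED)
    study += sd.random_peptides(40, seed=SEED + 10, prefix="bg")
    pio.write_fasta(study, OUT / "study.fasta")
    with open(OUT / "study_labels.tsv", "w") as fh:
        fh.write("id\tmajor\tminor\n")
        for p in study:
            if p.id.startswith("class0"):
                fh.write(f"{p.id}\tHA-RAMP\tsynthetic-class-I\n")
            elif p.id.startswith("class1"):
                fh.write(f"{p.id}\tTP\tmTP\n")
            else:
                fh.write(f"{p.id}\trandom\t\n")

    null = sd.random_peptides(200, seed=SEED)
    pio.write_fasta(null, OUT / "null.fasta")

    design = sd.designed_amphiphilic(18, 5, name="design18")
    controls = [design] + [sd.scramble(design, seed=s) for s in range(10)]
    pio.write_fasta(controls, OUT / "controls.fasta")

    print(f"study set: {len(study)} peptides (40 + 40 + 40), seed {SEED}")
    print(f"null set: {len(null)} random peptides")
    print(f"controls: designed 18-mer {design.sequence} + 10 scrambles")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
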