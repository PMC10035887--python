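"""Orthogroup container: one aligned amino-acid sequence per species.

An orthogroup is a set of one-to-one orthologous proteins, at most one
per species, aligned into a single MSA.  The human sequence anchors all
coordinate systems: alignment columns are 1-based indices into the MSA,
human positions are 1-based indices into the ungapped human sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

HUMAN = "Homo_sapiens"
GAP_CHARS = {"-", ".", "X"}
VALID_RESIDUES = set("ARNDCQEGHILKMFPSTWYV")


@dataclass
class Orthogroup:
    """Aligned one-to-one ortholog set keyed by species, human-anchored."""

    orthogroup_id: str
    sequences: dict[str, str]
    human_species: str = HUMAN
    gene: str = ""

    def __post_init__(self):
        if self.human_species not in self.sequences:
            raise ValueError(
                f"orthogroup {self.orthogroup_id}: human sequence "
                f"({self.human_species}) missing"
            )
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"orthogroup {self.orthogroup_id}: aligned sequences have "
                f"unequal lengths {sorted(lengths)}"
            )
        self.sequences = {sp: seq.upper() for sp, seq in self.sequences.items()}
        if not self.gene:
            self.gene = self.orthogroup_id

    @property
    def n_columns(self) -> int:
        return len(self.sequences[self.human_species])

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    @property
    def human_sequence(self) -> str:
        return self.sequences[self.human_species]

    def human_ungapped(self) -> str:
        return "".join(c for c in self.human_sequence if c not in GAP_CHARS)

    def column(self, index: int) -> dict[str, str]:
        """Residues at 1-based alignment column ``index``, per species."""
        i = index - 1
        return {sp: seq[i] for sp, seq in self.sequences.items()}

    def human_position_of_column(self) -> list[int | None]:
        """For each column (0-based list), the 1-based human position or None."""
        out: list[int | None] = []
        pos = 0
        for c in self.human_sequence:
            if c in GAP_CHARS:
                out.append(None)
            else:
                pos += 1
                out.append(pos)
        return out

    def restricted_to(self, species) -> "Orthogroup":
        keep = {sp: s for sp, s in self.sequences.items() if sp in set(species)}
        return Orthogroup(self.orthogroup_id, keep, self.human_species, self.gene)


def read_orthogroup_fasta(path, orthogroup_id=None, human_species=HUMAN) -> Orthogroup:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    seqs = {r.id: str(r.seq) for r in records}
    if orthogroup_id is None:
        import os

        orthogroup_id = os.path.splitext(os.path.basename(str(path)))[0]
    return Orthogroup(orthogroup_id, seqs, human_species=human_species)


def write_orthogroup_fasta(orthogroup: Orthogroup, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sp, description="")
        for sp, seq in orthogroup.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
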