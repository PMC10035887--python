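"""Orthogroup quality control and filtering.

Three filters guard the per-column analysis against misalignment:

1. **Pairwise similarity/gap filter** — each non-human sequence is
   globally aligned to the human sequence (Needleman-Wunsch, BLOSUM62,
   gap open 10 / extend 0.5, free end gaps — the EMBOSS Needle
   defaults).  A species is dropped when similarity (identical pairs
   plus positive-scoring, i.e. biochemically conservative, pairs, over
   the full alignment length) falls below 80% or gap columns exceed 10%.
2. **Match-state consistency** — a species whose residues are shifted
   out of register with the human domain match states (an internal gap
   at a match-state column with residues on both sides of it) is
   dropped: its domain positions are no longer homologous to the
   annotated human positions.
3. **Minimum size** — orthogroups with fewer than 10 retained sequences
   (human always counted) are rejected outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .ortho import GAP_CHARS, Orthogroup

SIMILARITY_THRESHOLD = 80.0
GAP_THRESHOLD = 10.0
MIN_ORTHOGROUP_SIZE = 10

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_BLOSUM62_ALPHABET = set(_BLOSUM62.alphabet)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    # Needle by default does not penalise end gaps
    aligner.end_gap_score = 0.0
    return aligner


def global_align_score(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Percent similarity and percent gaps of the global pairwise alignment.

    Similarity counts aligned pairs that are identical or score
    positively under BLOSUM62 (conservative substitutions); both
    percentages use the full alignment length, end gaps included.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    for seq in (seq_a, seq_b):
        bad = set(seq) - _BLOSUM62_ALPHABET
        if bad:
            raise ValueError(f"non-amino-acid characters in input: {sorted(bad)}")
    aligner = _make_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    a, b = str(alignment[0]), str(alignment[1])
    length = len(a)
    similar = gaps = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            gaps += 1
        elif x == y or _BLOSUM62[x, y] > 0:
            similar += 1
    return 100.0 * similar / length, 100.0 * gaps / length


def matchstate_check(
    orthogroup: Orthogroup, domain_matches: pd.DataFrame
) -> dict[str, bool]:
    """Per-species flag: True when domain match states stay in register.

    A species fails when it has a gap at an alignment column carrying a
    human domain match-state residue while having non-gap residues both
    before and after that column — an internal deletion or alignment
    shift that breaks match-state homology.  Terminal truncations and
    gaps outside domain spans are tolerated.
    """
    gene_matches = domain_matches[domain_matches["gene"] == orthogroup.gene]
    match_positions = set(gene_matches["human_position"].astype(int))
    pos_of_col = orthogroup.human_position_of_column()
    match_cols = [
        i for i, pos in enumerate(pos_of_col) if pos is not None and pos in match_positions
    ]
    flags: dict[str, bool] = {}
    for species, seq in orthogroup.sequences.items():
        if species == orthogroup.human_species or not match_cols:
            flags[species] = True
            continue
        residue_idx = [i for i, c in enumerate(seq) if c not in GAP_CHARS]
        if not residue_idx:
            flags[species] = False
            continue
        first, last = residue_idx[0], residue_idx[-1]
        ok = True
        for col in match_cols:
            if seq[col] in GAP_CHARS and first < col < last:
                ok = False
                break
        flags[species] = ok
    return flags


@dataclass
class QcReport:
    """Per-species QC outcomes for one orthogroup."""

    orthogroup_id: str
    table: pd.DataFrame  # species, similarity, gaps, matchstate_ok, retained, reason
    min_size: int = MIN_ORTHOGROUP_SIZE
    retained: bool = field(init=False)

    def __post_init__(self):
        self.retained = int(self.table["retained"].sum()) >= self.min_size

    @property
    def retained_species(self) -> list[str]:
        return list(self.table.loc[self.table["retained"], "species"])


def qc_orthogroup(
    orthogroup: Orthogroup,
    domain_matches: pd.DataFrame,
    similarity_threshold: float = SIMILARITY_THRESHOLD,
    gap_threshold: float = GAP_THRESHOLD,
    min_size: int = MIN_ORTHOGROUP_SIZE,
) -> QcReport:
    """Run all per-species checks against the human sequence."""
    human = orthogroup.human_ungapped()
    ms_flags = matchstate_check(orthogroup, domain_matches)
    rows = []
    for species, aligned in orthogroup.sequences.items():
        if species == orthogroup.human_species:
            similarity, gaps = 100.0, 0.0
        else:
            ungapped = "".join(c for c in aligned if c not in GAP_CHARS)
            similarity, gaps = global_align_score(human, ungapped)
        ms_ok = ms_flags[species]
        reasons = []
        if similarity < similarity_threshold:
            reasons.append("low_similarity")
        if gaps > gap_threshold:
            reasons.append("excess_gaps")
        if not ms_ok:
            reasons.append("matchstate_shift")
        if species == orthogroup.human_species:
            assert not reasons, "human sequence cannot fail self-comparison QC"
        rows.append(
            {
                "orthogroup": orthogroup.orthogroup_id,
                "species": species,
                "similarity": round(similarity, 4),
                "gaps": round(gaps, 4),
                "matchstate_ok": ms_ok,
                "retained": not reasons,
                "reason": ",".join(reasons),
            }
        )
    return QcReport(orthogroup.orthogroup_id, pd.DataFrame(rows), min_size=min_size)


def retained_size_histogram(qc_table: pd.DataFrame) -> pd.Series:
    """Histogram of retained orthogroup sizes over the reporting range 10-18.

    Rejected orthogroups (below the minimum size) are not counted.
    """
    sizes = qc_table.groupby("orthogroup")["retained"].sum().astype(int)
    sizes = sizes[sizes >= MIN_ORTHOGROUP_SIZE]
    return sizes.value_counts().reindex(range(10, 19), fill_value=0).sort_index()


def filter_orthogroup(
    orthogroup: Orthogroup, qc: QcReport
) -> tuple[Orthogroup | None, QcReport]:
    """Drop failing species; reject the orthogroup below 10 sequences."""
    if not qc.retained:
        return None, qc
    return orthogroup.restricted_to(qc.retained_species), qc
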