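"""Ligand-binding site annotation transfer.

Domain-level binding profiles give, for each (domain, ligand type) pair
and each match state of the domain model, the fraction ``f`` of
co-complex structures in which that position contacts the ligand, plus a
per-pair cross-validation precision ``p``.  A match state is classified
as *binding* when ``f >= 0.10`` and ``p`` clears the precision threshold
(0.50, raised to 0.75 for ions, whose coordination distances produce
more false contacts); *non-binding* when ``f = 0`` (never observed in
contact); everything in between is *excluded* from analysis.

Domain matches map match states onto 1-based human sequence positions;
classifications are transferred through those matches onto the human
sequence and then projected onto MSA columns, yielding the five column
classes used downstream: ``ligand_binding``, ``other_within_domain``,
``other_outside_domain``, ``excluded`` and (human-gap columns only)
``unannotated``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ortho import GAP_CHARS, Orthogroup

LIGAND_TYPES = ("DNA", "RNA", "small_molecule", "ion", "peptide")

BINDING_FREQ_CUTOFF = 0.10
PRECISION_CUTOFF = 0.50
PRECISION_CUTOFF_ION = 0.75

CLASS_BINDING = "ligand_binding"
CLASS_OTHER_DOMAIN = "other_within_domain"
CLASS_OTHER_OUTSIDE = "other_outside_domain"
CLASS_EXCLUDED = "excluded"
CLASS_UNANNOTATED = "unannotated"

SITE_CLASSES = (
    CLASS_BINDING,
    CLASS_OTHER_DOMAIN,
    CLASS_OTHER_OUTSIDE,
    CLASS_EXCLUDED,
    CLASS_UNANNOTATED,
)


def classify_domain_position(
    binding_frequency: float,
    cv_precision: float,
    ligand_type: str,
    freq_cutoff: float = BINDING_FREQ_CUTOFF,
    precision_cutoff: float = PRECISION_CUTOFF,
    precision_cutoff_ion: float = PRECISION_CUTOFF_ION,
) -> str:
    """Classify one (domain position, ligand) pair.

    Returns ``"binding"``, ``"non_binding"`` or ``"excluded"``.
    """
    f, p = float(binding_frequency), float(cv_precision)
    if not (0.0 <= f <= 1.0) or not (0.0 <= p <= 1.0):
        raise ValueError(f"binding frequency and precision must be in [0,1]; got f={f}, p={p}")
    if ligand_type not in LIGAND_TYPES:
        raise ValueError(f"unknown ligand type {ligand_type!r}")
    threshold = precision_cutoff_ion if ligand_type == "ion" else precision_cutoff
    if f >= freq_cutoff and p >= threshold:
        return "binding"
    if f == 0.0:
        return "non_binding"
    return "excluded"


@dataclass(frozen=True)
class PositionLabel:
    """Class and ligand set for one human sequence position."""

    site_class: str
    ligand_types: frozenset[str] = frozenset()


def transfer_annotations(
    gene: str,
    matches: pd.DataFrame,
    profiles: pd.DataFrame,
    seq_length: int,
    **thresholds,
) -> list[PositionLabel]:
    """Per-position labels (1-based order) for a human sequence.

    ``matches`` needs columns ``gene, domain_id, match_state,
    human_position``; ``profiles`` needs ``domain_id, ligand_type,
    match_state, binding_frequency, cv_precision``.  Where overlapping
    matches disagree, precedence is binding > excluded > non-binding: a
    position observed in contact with any ligand in any structure is a
    binding site.  Positions covered by no match become
    ``other_outside_domain``.
    """
    gene_matches = matches[matches["gene"] == gene]
    # profile lookup: (domain, match_state) -> list of (ligand, f, p)
    prof_idx: dict[tuple[str, int], list[tuple[str, float, float]]] = {}
    for row in profiles.itertuples(index=False):
        prof_idx.setdefault((row.domain_id, int(row.match_state)), []).append(
            (row.ligand_type, float(row.binding_frequency), float(row.cv_precision))
        )

    binding_ligands: dict[int, set[str]] = {}
    covered_class: dict[int, str] = {}  # best non-binding class seen
    for row in gene_matches.itertuples(index=False):
        pos = int(row.human_position)
        if not (1 <= pos <= seq_length):
            raise ValueError(
                f"{gene}: match position {pos} outside sequence (length {seq_length})"
            )
        key = (row.domain_id, int(row.match_state))
        entries = prof_idx.get(key)
        if entries is None:
            raise ValueError(
                f"{gene}: domain {row.domain_id} match state {row.match_state} "
                f"absent from binding profiles"
            )
        for ligand, f, p in entries:
            cls = classify_domain_position(f, p, ligand, **thresholds)
            if cls == "binding":
                binding_ligands.setdefault(pos, set()).add(ligand)
            elif cls == "excluded":
                if covered_class.get(pos) != CLASS_EXCLUDED:
                    covered_class[pos] = CLASS_EXCLUDED
            else:
                covered_class.setdefault(pos, CLASS_OTHER_DOMAIN)

    labels: list[PositionLabel] = []
    for pos in range(1, seq_length + 1):
        if pos in binding_ligands:
            labels.append(PositionLabel(CLASS_BINDING, frozenset(binding_ligands[pos])))
        elif pos in covered_class:
            labels.append(PositionLabel(covered_class[pos]))
        else:
            labels.append(PositionLabel(CLASS_OTHER_OUTSIDE))
    return labels


def project_to_columns(
    orthogroup: Orthogroup, human_labels: list[PositionLabel]
) -> pd.DataFrame:
    """Site-annotation table: one row per MSA column, human-anchored.

    Columns where the human sequence has a gap are ``unannotated``.
    Returns a DataFrame with ``orthogroup, column, human_position, class,
    ligand_types`` (ligand types comma-joined, empty for non-binding).
    """
    ungapped = orthogroup.human_ungapped()
    if len(ungapped) != len(human_labels):
        raise ValueError(
            f"label vector length {len(human_labels)} != ungapped human "
            f"length {len(ungapped)}"
        )
    positions = orthogroup.human_position_of_column()
    rows = []
    for col0, pos in enumerate(positions):
        if pos is None:
            rows.append(
                {
                    "orthogroup": orthogroup.orthogroup_id,
                    "column": col0 + 1,
                    "human_position": pd.NA,
                    "class": CLASS_UNANNOTATED,
                    "ligand_types": "",
                }
            )
        else:
            lab = human_labels[pos - 1]
            rows.append(
                {
                    "orthogroup": orthogroup.orthogroup_id,
                    "column": col0 + 1,
                    "human_position": pos,
                    "class": lab.site_class,
                    "ligand_types": ",".join(sorted(lab.ligand_types)),
                }
            )
    return pd.DataFrame(rows)


def read_domtblout_matches(path, gene_of_target=None) -> pd.DataFrame:
    """Build a domain-match table from an HMMER ``--domtblout`` file.

    Only hits whose HMM span and alignment span have equal length are
    mapped (a colinear, gap-free match-state -> position mapping); hits
    with indels need the full alignment and are skipped.
    ``gene_of_target`` optionally maps target sequence names to gene
    identifiers (defaults to the target name itself).
    """
    rows = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split()
            target, query = fields[0], fields[3]
            hmm_from, hmm_to = int(fields[15]), int(fields[16])
            ali_from, ali_to = int(fields[17]), int(fields[18])
            if hmm_to - hmm_from != ali_to - ali_from:
                continue  # gapped hit; mapping not colinear
            gene = gene_of_target(target) if gene_of_target else target
            for offset in range(hmm_to - hmm_from + 1):
                rows.append(
                    {
                        "gene": gene,
                        "domain_id": query,
                        "match_state": hmm_from + offset,
                        "human_position": ali_from + offset,
                    }
                )
    return pd.DataFrame(rows, columns=["gene", "domain_id", "match_state", "human_position"])


def annotate_orthogroup(
    orthogroup: Orthogroup,
    matches: pd.DataFrame,
    profiles: pd.DataFrame,
    **thresholds,
) -> pd.DataFrame:
    """Transfer profile classifications onto an orthogroup's MSA columns."""
    labels = transfer_annotations(
        orthogroup.gene,
        matches,
        profiles,
        seq_length=len(orthogroup.human_ungapped()),
        **thresholds,
    )
    return project_to_columns(orthogroup, labels)
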