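"""Lineage-specific fixed binding-site detection.

Scans ligand-binding MSA columns for residues unique to a focal clade
(human, or the great apes):

* **strict** — all focal taxa carry one residue X, all non-focal taxa
  carry one (different) residue Y; the change is fixed on both sides of
  the split;
* **relaxed** — the focal taxa still share a single residue X, but the
  non-focal taxa may vary freely as long as none of them carries X.

Columns with any gap among the retained species are skipped: a residue
cannot be called fixed across taxa that lack data.  Candidates are then
filtered against human population variation: a site survives only if
every overlapping variant is rare (allele frequency <= 0.01) and not
disease-flagged, so the human residue is effectively fixed within the
human population as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .annotation import CLASS_BINDING
from .ortho import GAP_CHARS, Orthogroup

logger = logging.getLogger(__name__)

MAF_THRESHOLD = 0.01

MODES = ("strict", "relaxed")


@dataclass
class FixedSiteCall:
    """One candidate lineage-specific binding-site change."""

    gene: str
    orthogroup: str
    column: int
    human_position: int
    ligand_types: str
    focal_residue: str
    background_residues: str
    mode: str
    population_pass: bool | None = None
    reason: str = ""


def scan_lineage_specific(
    orthogroup: Orthogroup,
    annotation: pd.DataFrame,
    focal_taxa,
    mode: str = "strict",
) -> list[FixedSiteCall]:
    """All qualifying ligand-binding columns for one orthogroup.

    ``annotation`` is the per-column site-annotation table for this
    orthogroup.  ``focal_taxa`` must all be present in the (already
    QC-filtered) orthogroup; otherwise the orthogroup is skipped with a
    log entry and no calls are returned.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    focal = set(focal_taxa)
    present = set(orthogroup.species)
    if not focal <= present:
        logger.info(
            "orthogroup %s skipped: focal taxa %s not retained",
            orthogroup.orthogroup_id,
            sorted(focal - present),
        )
        return []
    background = present - focal
    if not background:
        raise ValueError("focal clade covers every retained species")

    binding = annotation[annotation["class"] == CLASS_BINDING]
    calls: list[FixedSiteCall] = []
    for row in binding.itertuples(index=False):
        col = int(row.column)
        residues = orthogroup.column(col)
        if any(r in GAP_CHARS for r in residues.values()):
            continue
        focal_res = {residues[sp] for sp in focal}
        back_res = {residues[sp] for sp in background}
        if len(focal_res) != 1:
            continue
        (x,) = focal_res
        if mode == "strict":
            qualifies = len(back_res) == 1 and x not in back_res
        else:
            qualifies = x not in back_res
        if qualifies:
            clade = "human" if focal == {orthogroup.human_species} else "ape"
            mode_label = f"{clade}_{mode}"
            calls.append(
                FixedSiteCall(
                    gene=orthogroup.gene,
                    orthogroup=orthogroup.orthogroup_id,
                    column=col,
                    human_position=int(row.human_position),
                    ligand_types=row.ligand_types,
                    focal_residue=x,
                    background_residues="".join(sorted(back_res)),
                    mode=mode_label,
                )
            )
    return calls


def apply_population_filter(
    candidates: list[FixedSiteCall],
    variants: pd.DataFrame,
    maf_threshold: float = MAF_THRESHOLD,
) -> list[FixedSiteCall]:
    """Set ``population_pass`` on each candidate from the variant table.

    A candidate passes iff every variant at its (gene, human position)
    has allele frequency <= ``maf_threshold`` and is not disease-flagged;
    candidates with no overlapping variant pass.  Matching is by site,
    not by allele.
    """
    by_site: dict[tuple[str, int], list] = {}
    for row in variants.itertuples(index=False):
        by_site.setdefault((row.gene, int(row.position)), []).append(row)
    out = []
    for call in candidates:
        overlapping = by_site.get((call.gene, call.human_position), [])
        reasons = []
        for v in overlapping:
            if float(v.allele_frequency) > maf_threshold:
                reasons.append("common_variant")
            if bool(v.disease_flag):
                reasons.append("disease_variant")
        call.population_pass = not reasons
        call.reason = ",".join(sorted(set(reasons)))
        out.append(call)
    return out


def calls_to_frame(calls: list[FixedSiteCall]) -> pd.DataFrame:
    cols = [
        "gene",
        "orthogroup",
        "column",
        "human_position",
        "mode",
        "focal_residue",
        "background_residues",
        "ligand_types",
        "population_pass",
        "reason",
    ]
    return pd.DataFrame([{c: getattr(x, c) for c in cols} for x in calls], columns=cols)
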