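"""Variable-interface genes, fold enrichment and GO over-representation.

Identifies genes whose ligand-binding interfaces vary across the
primates (excluding sites with common human variation, allele frequency
> 0.01, which are likely neutral), computes each protein's fold
enrichment of binding-site variability over its own within-domain
background, and tests a study gene set for over-represented annotation
terms against the ligand-binding background with a one-sided
hypergeometric test and Benjamini-Hochberg FDR control.

Fold enrichment for one protein is
``F = (variable binding / binding) / (variable other-in-domain /
other-in-domain)``; a protein qualifies as a variable-interface
candidate when ``F >= 2`` and it has at least two variable binding
sites.  A zero background with variable binding sites gives ``F = inf``
(sorted above all finite values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation import CLASS_BINDING, CLASS_OTHER_DOMAIN

FOLD_THRESHOLD = 2.0
MIN_VARIABLE_BINDING = 2
FDR_THRESHOLD = 0.05
MAF_THRESHOLD = 0.01


# ------------------------------------------------- variable-interface set


def variable_interface_genes(
    site_table: pd.DataFrame,
    variants: pd.DataFrame,
    maf_threshold: float = MAF_THRESHOLD,
) -> set[str]:
    """Genes with >= 1 variable binding column free of common variation.

    The filter is per site: a gene stays in the set as long as any one
    of its variable binding sites has no overlapping variant with
    allele frequency above the threshold.
    """
    common = {
        (row.gene, int(row.position))
        for row in variants.itertuples(index=False)
        if float(row.allele_frequency) > maf_threshold
    }
    t = site_table[
        (site_table["class"] == CLASS_BINDING)
        & (site_table["variable"] == True)  # noqa: E712 - may hold NA
        & site_table["human_position"].notna()
    ]
    out = set()
    for row in t.itertuples(index=False):
        if (row.gene, int(row.human_position)) not in common:
            out.add(row.gene)
    return out


# --------------------------------------------------------- fold enrichment


@dataclass
class FoldEnrichmentRecord:
    gene: str
    n_binding: int
    n_binding_variable: int
    n_other_domain: int
    n_other_domain_variable: int
    fold: float  # may be inf
    qualifies: bool
    evaluable: bool = True


def fold_enrichment(
    gene: str,
    n_binding: int,
    n_binding_variable: int,
    n_other_domain: int,
    n_other_domain_variable: int,
    fold_threshold: float = FOLD_THRESHOLD,
    min_variable: int = MIN_VARIABLE_BINDING,
) -> FoldEnrichmentRecord:
    """Per-protein fold enrichment of binding-site variability."""
    if n_binding == 0:
        return FoldEnrichmentRecord(
            gene, 0, 0, n_other_domain, n_other_domain_variable,
            float("nan"), False, evaluable=False,
        )
    if n_other_domain == 0:
        return FoldEnrichmentRecord(
            gene, n_binding, n_binding_variable, 0, 0,
            float("nan"), False, evaluable=False,
        )
    binding_frac = n_binding_variable / n_binding
    other_frac = n_other_domain_variable / n_other_domain
    if other_frac == 0:
        fold = float("inf") if binding_frac > 0 else float("nan")
    else:
        fold = binding_frac / other_frac
    qualifies = (
        fold == fold and fold >= fold_threshold and n_binding_variable >= min_variable
    )
    return FoldEnrichmentRecord(
        gene, n_binding, n_binding_variable, n_other_domain,
        n_other_domain_variable, fold, bool(qualifies),
    )


def fold_enrichment_table(site_table: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Fold-enrichment records for every gene in a pooled site table."""
    rows = []
    for gene, sub in site_table.dropna(subset=["variable"]).groupby("gene"):
        binding = sub[sub["class"] == CLASS_BINDING]
        other = sub[sub["class"] == CLASS_OTHER_DOMAIN]
        rec = fold_enrichment(
            gene,
            len(binding),
            int(binding["variable"].astype(bool).sum()),
            len(other),
            int(other["variable"].astype(bool).sum()),
            **kwargs,
        )
        rows.append(vars(rec))
    frame = pd.DataFrame(
        rows,
        columns=[
            "gene", "n_binding", "n_binding_variable", "n_other_domain",
            "n_other_domain_variable", "fold", "qualifies", "evaluable",
        ],
    )
    return frame.sort_values(
        "fold", ascending=False, na_position="last", kind="stable"
    ).reset_index(drop=True)


# ------------------------------------------------------- over-representation


def go_overrepresentation(
    study: set[str],
    background: set[str],
    annotations: pd.DataFrame,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH-FDR.

    ``annotations`` maps genes to terms (columns ``gene``, ``term_id``).
    Only annotations of background genes are considered; terms with no
    study hits are skipped.  Returns one row per tested term with the
    hypergeometric upper-tail p and BH-adjusted FDR, sorted by p.
    """
    study, background = set(study), set(background)
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    ann = annotations[annotations["gene"].isin(background)]
    n_bg = len(background)
    n_study = len(study)
    rows = []
    for term, sub in ann.groupby("term_id"):
        term_genes = set(sub["gene"])
        k_study = len(term_genes & study)
        if k_study == 0:
            continue
        k_bg = len(term_genes)
        p = float(hypergeom.sf(k_study - 1, n_bg, k_bg, n_study))
        rows.append(
            {
                "term_id": term,
                "study_k": k_study,
                "study_n": n_study,
                "bg_k": k_bg,
                "bg_n": n_bg,
                "p": p,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["term_id", "study_k", "study_n", "bg_k", "bg_n", "p"]
    )
    if len(frame):
        frame["fdr"] = multipletests(frame["p"], method="fdr_bh")[1]
        frame["significant"] = frame["fdr"] < fdr_threshold
        frame = frame.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        frame["fdr"] = pd.Series(dtype=float)
        frame["significant"] = pd.Series(dtype=bool)
    return frame
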