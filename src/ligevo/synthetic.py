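"""Synthetic dataset generation with known ground truth.

Every downstream stage of the pipeline can be exercised on simulated
data in which the quantities the analysis tries to recover are planted
by construction:

* binding profiles with a known fraction of match states above the
  binding thresholds;
* orthogroups evolved site-independently along the fixed species tree
  under an empirical amino-acid model, with per-site rates drawn from a
  gamma distribution (mean one) and multiplied by
  ``rate_multiplier_binding`` at binding sites — a multiplier below one
  plants the "binding sites evolve more slowly" structure, one gives the
  null, zero freezes binding columns;
* human-specific substitutions planted at binding columns that are
  monomorphic in the other species (the strict scanner's definition);
* a population-variant table in which planted sites carry only rare
  (allele frequency <= 0.01), non-disease variants;
* a gene->GO annotation table with one term planted on a chosen gene
  set.

Simulation is insertion/deletion-free: columns align trivially, so
alignment inference never confounds parameter recovery.  All outputs
are deterministic functions of the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import LIGAND_TYPES, CLASS_BINDING, annotate_orthogroup
from .ortho import Orthogroup, HUMAN
from .phylo import PrimatePhylogeny, load_reference_tree
from .sitemetrics import classify_variability
from .substitution import AMINO_ACIDS, SubstitutionModel

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "generate_binding_profiles",
    "simulate_orthogroup",
    "generate_population_variants",
    "generate_go_annotations",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic run.

    ``rate_multiplier_binding`` scales per-site rates at binding columns
    (0.5 by default: binding sites evolve at half the background rate);
    ``gamma_shape`` controls rate heterogeneity (gamma with mean one);
    ``variant_maf_mix`` sets the chance a position carries a variant,
    the fraction of variants that are common (AF > 0.01), and the
    chance a variant is disease-flagged.
    """

    n_orthogroups: int = 20
    seq_length_range: tuple[int, int] = (150, 300)
    domain_density: float = 0.5
    rate_multiplier_binding: float = 0.5
    gamma_shape: float = 1.0
    n_planted_human_specific: int = 0
    variant_maf_mix: tuple[float, float, float] = (0.05, 0.10, 0.05)
    subst_model: str = "JTT"
    sim_model: str | None = None  # mismatched-model mode if different
    seed: int = 0

    def __post_init__(self):
        if self.rate_multiplier_binding < 0:
            raise ValueError("rate_multiplier_binding must be >= 0")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.seq_length_range[0] > self.seq_length_range[1]:
            raise ValueError("seq_length_range must be (lo, hi) with lo <= hi")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ------------------------------------------------------------- profiles


def generate_binding_profiles(
    n_domains: int,
    length_range: tuple[int, int] = (30, 60),
    seed=0,
    p_binding: float = 0.2,
    p_nonbinding: float = 0.6,
    second_ligand_prob: float = 0.25,
) -> pd.DataFrame:
    """Per-domain-position binding-frequency table.

    Each domain gets one (sometimes two) ligand types; per match state
    the binding frequency is >= 0.10 with probability ``p_binding``,
    exactly 0 with probability ``p_nonbinding``, and in (0, 0.10)
    otherwise.  Cross-validation precision is drawn once per
    (domain, ligand) pair from U(0.4, 1.0), so a minority of domains
    fall below the admission threshold entirely.
    """
    if n_domains < 1:
        raise ValueError("n_domains must be >= 1")
    rng = _rng(seed)
    rows = []
    for d in range(n_domains):
        domain_id = f"DOM{d:04d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        ligands = [LIGAND_TYPES[rng.integers(len(LIGAND_TYPES))]]
        if rng.random() < second_ligand_prob:
            other = [l for l in LIGAND_TYPES if l not in ligands]
            ligands.append(other[rng.integers(len(other))])
        for ligand in ligands:
            precision = float(rng.uniform(0.4, 1.0))
            u = rng.random(length)
            freqs = np.empty(length)
            is_binding = u < p_binding
            is_nonbinding = (u >= p_binding) & (u < p_binding + p_nonbinding)
            freqs[is_binding] = rng.uniform(0.10, 1.0, is_binding.sum())
            freqs[is_nonbinding] = 0.0
            rest = ~(is_binding | is_nonbinding)
            freqs[rest] = rng.uniform(0.001, 0.0999, rest.sum())
            for ms in range(1, length + 1):
                rows.append(
                    {
                        "domain_id": domain_id,
                        "ligand_type": ligand,
                        "match_state": ms,
                        "binding_frequency": round(float(freqs[ms - 1]), 6),
                        "cv_precision": round(precision, 6),
                    }
                )
    return pd.DataFrame(rows)


# ------------------------------------------------------------ evolution


def _evolve_states(
    tree: PrimatePhylogeny,
    model: SubstitutionModel,
    rates: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Evolve integer-coded sequences down the tree; returns leaf states."""
    arrays = tree.to_arrays()
    n_sites = rates.size
    root_states = rng.choice(20, size=n_sites, p=model.pi)
    states: dict[int, np.ndarray] = {arrays.root: root_states}
    stack = [arrays.root]
    while stack:
        node = stack.pop()
        parent_states = states[node]
        for child in arrays.children[node]:
            p = model.transition_matrices(rates * arrays.blen[child])
            probs = p[np.arange(n_sites), parent_states, :]
            u = rng.random(n_sites)
            child_states = (probs.cumsum(axis=1) > u[:, None]).argmax(axis=1)
            states[child] = child_states
            if arrays.children[child]:
                stack.append(child)
    return {
        name: states[i] for i, name in enumerate(arrays.leaf_names)
    }


def simulate_orthogroup(
    tree: PrimatePhylogeny,
    profiles: pd.DataFrame,
    cfg: SimulationConfig,
    seed=None,
    orthogroup_id: str = "OG0000",
    gene: str | None = None,
) -> tuple[Orthogroup, pd.DataFrame, pd.DataFrame]:
    """Simulate one orthogroup; returns (orthogroup, matches, ground_truth).

    Domain instances (at most one per domain model) are laid along the
    human sequence up to ``domain_density`` coverage; site classes come
    from the same annotation-transfer logic the analysis uses.  True
    per-site rates are gamma draws scaled by the binding multiplier at
    binding columns.  Planted human-specific substitutions overwrite the
    human residue with an amino acid absent from the column, at binding
    columns monomorphic across the other species.
    """
    rng = _rng(cfg.seed if seed is None else seed)
    gene = gene or orthogroup_id
    lo, hi = cfg.seq_length_range
    length = int(rng.integers(lo, hi + 1))

    # lay out non-overlapping domain instances
    domain_lengths = profiles.groupby("domain_id")["match_state"].max().to_dict()
    domain_ids = sorted(domain_lengths)
    rng.shuffle(domain_ids)
    match_rows = []
    cursor = 1 + int(rng.integers(0, 10))
    covered = 0
    for domain_id in domain_ids:
        dlen = int(domain_lengths[domain_id])
        if covered >= cfg.domain_density * length:
            break
        if cursor + dlen - 1 > length:
            continue
        for ms in range(1, dlen + 1):
            match_rows.append(
                {
                    "gene": gene,
                    "domain_id": domain_id,
                    "match_state": ms,
                    "human_position": cursor + ms - 1,
                }
            )
        covered += dlen
        cursor += dlen + int(rng.integers(2, 12))
    matches = pd.DataFrame(
        match_rows, columns=["gene", "domain_id", "match_state", "human_position"]
    )

    # classify positions exactly as the analysis will
    template = Orthogroup(orthogroup_id, {HUMAN: "A" * length}, gene=gene)
    annotation = annotate_orthogroup(template, matches, profiles)
    site_class = annotation["class"].to_numpy()
    ligand_types = annotation["ligand_types"].to_numpy()
    is_binding = site_class == CLASS_BINDING

    # plant rate structure and evolve
    true_rates = rng.gamma(cfg.gamma_shape, 1.0 / cfg.gamma_shape, size=length)
    true_rates[is_binding] *= cfg.rate_multiplier_binding
    sim_model = SubstitutionModel.from_name(cfg.sim_model or cfg.subst_model)
    leaf_states = _evolve_states(tree, sim_model, true_rates, rng)

    sequences = {
        name: "".join(AMINO_ACIDS[s] for s in states)
        for name, states in leaf_states.items()
    }

    # plant human-specific substitutions
    planted = np.zeros(length, dtype=bool)
    if cfg.n_planted_human_specific > 0:
        others = [sp for sp in sequences if sp != HUMAN]
        eligible = [
            i
            for i in np.flatnonzero(is_binding)
            if len({sequences[sp][i] for sp in others}) == 1
        ]
        if len(eligible) < cfg.n_planted_human_specific:
            raise ValueError(
                f"{orthogroup_id}: requested {cfg.n_planted_human_specific} planted "
                f"human-specific sites but only {len(eligible)} eligible binding "
                f"columns are available"
            )
        chosen = rng.choice(eligible, size=cfg.n_planted_human_specific, replace=False)
        human = list(sequences[HUMAN])
        for i in sorted(int(c) for c in chosen):
            present = {sequences[sp][i] for sp in sequences}
            absent = sorted(set(AMINO_ACIDS) - present)
            human[i] = absent[rng.integers(len(absent))]
            planted[i] = True
        sequences[HUMAN] = "".join(human)

    orthogroup = Orthogroup(orthogroup_id, sequences, gene=gene)
    ground_truth = pd.DataFrame(
        {
            "gene": gene,
            "orthogroup": orthogroup_id,
            "column": np.arange(1, length + 1),
            "true_rate": true_rates,
            "class": site_class,
            "ligand_types": ligand_types,
            "planted_human_specific": planted,
        }
    )
    return orthogroup, matches, ground_truth


# -------------------------------------------------------------- variants


def generate_population_variants(
    orthogroups: list[Orthogroup],
    ground_truth: pd.DataFrame,
    cfg: SimulationConfig,
    seed=0,
) -> pd.DataFrame:
    """Synthetic population-variant extract (gnomAD-like TSV schema).

    Positions carry a variant with probability ``p_variant``; a variant
    is common (AF drawn in (0.01, 0.5]) with probability ``p_common``
    and rare (log-uniform in [1e-5, 0.01]) otherwise; rare variants are
    disease-flagged with probability ``p_disease``.  Planted
    human-specific sites only ever receive rare, non-disease variants.
    """
    rng = _rng(seed)
    p_variant, p_common, p_disease = cfg.variant_maf_mix
    planted_positions = {
        (row.gene, int(row.column))
        for row in ground_truth.itertuples(index=False)
        if row.planted_human_specific
    }
    rows = []
    for og in orthogroups:
        human = og.human_ungapped()
        for pos in range(1, len(human) + 1):
            if rng.random() >= p_variant:
                continue
            ref = human[pos - 1]
            alt = AMINO_ACIDS[rng.integers(20)]
            while alt == ref:
                alt = AMINO_ACIDS[rng.integers(20)]
            is_planted = (og.gene, pos) in planted_positions
            common = (not is_planted) and rng.random() < p_common
            if common:
                af = float(rng.uniform(0.011, 0.5))
                disease = False
            else:
                af = float(10 ** rng.uniform(-5, np.log10(0.01)))
                disease = (not is_planted) and rng.random() < p_disease
            rows.append(
                {
                    "gene": og.gene,
                    "position": pos,
                    "ref_aa": ref,
                    "alt_aa": alt,
                    "allele_frequency": round(af, 8),
                    "disease_flag": disease,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "position", "ref_aa", "alt_aa", "allele_frequency", "disease_flag"],
    )


# ------------------------------------------------------------------- GO


def generate_go_annotations(
    genes: list[str],
    n_terms: int = 20,
    planted_term: str | None = None,
    planted_genes: list[str] | None = None,
    seed=0,
    base_rate: float = 0.05,
) -> pd.DataFrame:
    """Gene->term annotation table with an optional planted enrichment.

    Background terms annotate each gene independently at ``base_rate``;
    the planted term (if any) annotates every planted gene plus the
    base-rate background.
    """
    rng = _rng(seed)
    planted_genes = list(planted_genes or [])
    unknown = set(planted_genes) - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in gene list: {sorted(unknown)}")
    rows = []
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    for term in terms:
        for gene in genes:
            if rng.random() < base_rate:
                rows.append({"gene": gene, "term_id": term})
    if planted_term is not None:
        annotated = set(planted_genes)
        for gene in genes:
            if gene in annotated or rng.random() < base_rate:
                rows.append({"gene": gene, "term_id": planted_term})
    return pd.DataFrame(rows, columns=["gene", "term_id"])


# ------------------------------------------------------------- datasets


@dataclass
class SyntheticDataset:
    """A complete simulated input set plus its ground truth."""

    config: SimulationConfig
    tree: PrimatePhylogeny
    profiles: pd.DataFrame
    orthogroups: list[Orthogroup]
    matches: pd.DataFrame
    ground_truth: pd.DataFrame
    variants: pd.DataFrame
    go_annotations: pd.DataFrame
    planted_go_term: str | None = None


def generate_dataset(
    cfg: SimulationConfig,
    tree: PrimatePhylogeny | None = None,
    n_domains: int = 40,
    plant_go_term: bool = True,
) -> SyntheticDataset:
    """Generate tree, profiles, orthogroups, variants and GO annotations.

    When ``plant_go_term`` is set, the term ``GO:PLANTED`` is annotated
    on every gene that ends up with at least one variable binding
    column, so the downstream over-representation stage has a true
    positive to recover.
    """
    rng = _rng(cfg.seed)
    tree = tree or load_reference_tree()
    profiles = generate_binding_profiles(n_domains, seed=rng)
    orthogroups, match_frames, truth_frames = [], [], []
    for k in range(cfg.n_orthogroups):
        og, matches, truth = simulate_orthogroup(
            tree, profiles, cfg, seed=rng, orthogroup_id=f"OG{k:04d}", gene=f"GENE{k:04d}"
        )
        orthogroups.append(og)
        match_frames.append(matches)
        truth_frames.append(truth)
    matches = pd.concat(match_frames, ignore_index=True)
    ground_truth = pd.concat(truth_frames, ignore_index=True)
    variants = generate_population_variants(orthogroups, ground_truth, cfg, seed=rng)

    genes = [og.gene for og in orthogroups]
    planted_term = None
    planted_genes: list[str] = []
    if plant_go_term:
        planted_term = "GO:PLANTED"
        for og in orthogroups:
            ann = ground_truth[ground_truth["gene"] == og.gene]
            binding_cols = ann.loc[ann["class"] == CLASS_BINDING, "column"]
            for col in binding_cols:
                if classify_variability(og.column(int(col))) == "variable":
                    planted_genes.append(og.gene)
                    break
    go = generate_go_annotations(
        genes, planted_term=planted_term, planted_genes=planted_genes, seed=rng
    )
    return SyntheticDataset(
        cfg, tree, profiles, orthogroups, matches, ground_truth, variants, go,
        planted_go_term=planted_term,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write a dataset to disk in the pipeline's on-disk formats."""
    import os

    from .ortho import write_orthogroup_fasta

    os.makedirs(outdir, exist_ok=True)
    msa_dir = os.path.join(outdir, "msa")
    os.makedirs(msa_dir, exist_ok=True)
    for og in dataset.orthogroups:
        write_orthogroup_fasta(og, os.path.join(msa_dir, f"{og.orthogroup_id}.fasta"))
    dataset.tree.write(os.path.join(outdir, "tree.nwk"))
    kw = dict(sep="\t", index=False)
    dataset.profiles.to_csv(os.path.join(outdir, "binding_profiles.tsv"), **kw)
    dataset.matches.to_csv(os.path.join(outdir, "domain_matches.tsv"), **kw)
    dataset.ground_truth.to_csv(os.path.join(outdir, "ground_truth.tsv"), **kw)
    dataset.variants.to_csv(os.path.join(outdir, "variants.tsv"), **kw)
    dataset.go_annotations.to_csv(os.path.join(outdir, "go_annotations.tsv"), **kw)
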