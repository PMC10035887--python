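"""Simulation studies validating the estimator and test battery.

Three standard checks, each run on synthetic data with known ground
truth:

* **rate recovery** — with binding sites planted at half the background
  rate and at least 200 sites per class, the estimated rates should
  separate the classes (Mann-Whitney U) and correlate with the true
  per-site rates (Spearman);
* **null calibration** — with the binding multiplier at 1 nothing is
  planted, so the Fisher and Mann-Whitney comparisons should reject at
  the nominal level;
* **planted-site recovery** — every planted human-specific binding site
  must be found by the strict scanner and survive the population
  filter, and a site carrying a common variant must be filtered out.

All experiments run under the generator's default conditions (binding
annotation density, gamma rate heterogeneity, the packaged tree);
orthogroups are pooled until each site class reaches the required
count.  See the methods note for the chosen problem sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .annotation import CLASS_BINDING, annotate_orthogroup
from .ortho import Orthogroup
from .phylo import PrimatePhylogeny, load_reference_tree
from .scan import apply_population_filter, scan_lineage_specific
from .sitemetrics import classify_variability, estimate_site_rates
from .stats import fisher_exact_2x2, mann_whitney_u
from .synthetic import (
    SimulationConfig,
    generate_binding_profiles,
    generate_population_variants,
    simulate_orthogroup,
)

def _simulate_pool(
    tree: PrimatePhylogeny,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    min_per_class: int,
    max_orthogroups: int = 12,
):
    """Simulate orthogroups until both site classes reach ``min_per_class``."""
    profiles = generate_binding_profiles(30, seed=rng)
    true_rates, est_rates, is_binding, variable = [], [], [], []
    n_binding = n_other = 0
    for k in range(max_orthogroups):
        og, _, truth = simulate_orthogroup(
            tree, profiles, cfg, seed=rng, orthogroup_id=f"OG{k}", gene=f"G{k}"
        )
        rates = estimate_site_rates(og, tree)
        binding = (truth["class"] == CLASS_BINDING).to_numpy()
        var = np.array(
            [
                classify_variability(og.column(c)) == "variable"
                for c in range(1, og.n_columns + 1)
            ]
        )
        true_rates.append(truth["true_rate"].to_numpy())
        est_rates.append(rates)
        is_binding.append(binding)
        variable.append(var)
        n_binding += int(binding.sum())
        n_other += int((~binding).sum())
        if n_binding >= min_per_class and n_other >= min_per_class:
            break
    return (
        np.concatenate(true_rates),
        np.concatenate(est_rates),
        np.concatenate(is_binding),
        np.concatenate(variable),
    )


@dataclass
class RecoveryResult:
    n_seeds: int
    sites_per_class: int
    frac_mwu_significant: float
    frac_spearman_ok: float
    mean_spearman: float
    spearman_values: list[float]
    mwu_pvalues: list[float]


def rate_recovery_experiment(
    n_seeds: int = 50,
    sites_per_class: int = 200,
    rate_multiplier: float = 0.5,
    base_seed: int = 0,
    spearman_threshold: float = 0.6,
    mwu_alpha: float = 0.01,
) -> RecoveryResult:
    """Recover planted rate structure over independent simulation seeds."""
    tree = load_reference_tree()
    rhos, pvals, n_sig, n_rho_ok = [], [], 0, 0
    for s in range(n_seeds):
        rng = np.random.default_rng((base_seed + 10_000 * s) % 2**31)
        cfg = SimulationConfig(
            seq_length_range=(350, 350),
            rate_multiplier_binding=rate_multiplier,
            seed=0,
        )
        truth, est, binding, _ = _simulate_pool(tree, cfg, rng, sites_per_class)
        rho = float(spearmanr(truth, est).statistic)
        p = mann_whitney_u(est[binding], est[~binding])
        lower = est[binding].mean() < est[~binding].mean()
        rhos.append(rho)
        pvals.append(p)
        n_sig += int(p < mwu_alpha and lower)
        n_rho_ok += int(rho >= spearman_threshold)
    return RecoveryResult(
        n_seeds=n_seeds,
        sites_per_class=sites_per_class,
        frac_mwu_significant=n_sig / n_seeds,
        frac_spearman_ok=n_rho_ok / n_seeds,
        mean_spearman=float(np.mean(rhos)),
        spearman_values=rhos,
        mwu_pvalues=pvals,
    )


@dataclass
class CalibrationResult:
    n_replicates: int
    fisher_rejection_rate: float
    mwu_rejection_rate: float


def null_calibration_experiment(
    n_replicates: int = 200,
    sites_per_class: int = 60,
    alpha: float = 0.05,
    base_seed: int = 1,
) -> CalibrationResult:
    """Type-I error of the class comparisons under the null (multiplier 1)."""
    tree = load_reference_tree()
    fisher_rej = mwu_rej = 0
    for s in range(n_replicates):
        rng = np.random.default_rng((base_seed + 20_000 * s) % 2**31)
        cfg = SimulationConfig(
            seq_length_range=(300, 300),
            rate_multiplier_binding=1.0,
            seed=0,
        )
        _, est, binding, variable = _simulate_pool(
            tree, cfg, rng, sites_per_class, max_orthogroups=4
        )
        table = np.array(
            [
                [int((~variable[binding]).sum()), int(variable[binding].sum())],
                [int((~variable[~binding]).sum()), int(variable[~binding].sum())],
            ]
        )
        fisher_rej += int(fisher_exact_2x2(table) < alpha)
        mwu_rej += int(mann_whitney_u(est[binding], est[~binding]) < alpha)
    return CalibrationResult(
        n_replicates=n_replicates,
        fisher_rejection_rate=fisher_rej / n_replicates,
        mwu_rejection_rate=mwu_rej / n_replicates,
    )


@dataclass
class PlantedScanResult:
    n_planted: int
    n_recovered: int
    sensitivity: float
    common_variant_excluded: bool


def planted_scan_experiment(
    n_orthogroups: int = 6,
    planted_per_orthogroup: int = 2,
    base_seed: int = 2,
) -> PlantedScanResult:
    """Strict-scanner sensitivity on planted human-specific binding sites.

    Also verifies the population filter: a copy of one planted site is
    given a common (AF > 0.01) variant and must be excluded.
    """
    tree = load_reference_tree()
    rng = np.random.default_rng(base_seed % 2**31)
    profiles = generate_binding_profiles(30, seed=rng)
    cfg = SimulationConfig(
        seq_length_range=(300, 300),
        n_planted_human_specific=planted_per_orthogroup,
        seed=0,
    )
    orthogroups, truths, matches_frames = [], [], []
    for k in range(n_orthogroups):
        og, matches, truth = simulate_orthogroup(
            tree, profiles, cfg, seed=rng, orthogroup_id=f"OG{k}", gene=f"G{k}"
        )
        orthogroups.append(og)
        truths.append(truth)
        matches_frames.append(matches)
    truth = pd.concat(truths, ignore_index=True)
    all_matches = pd.concat(matches_frames, ignore_index=True)
    variants = generate_population_variants(orthogroups, truth, cfg, seed=rng)

    planted = {
        (r.gene, int(r.column))
        for r in truth.itertuples(index=False)
        if r.planted_human_specific
    }
    recovered = set()
    all_calls = []
    for og in orthogroups:
        ann = annotate_orthogroup(og, all_matches, profiles)
        calls = scan_lineage_specific(og, ann, {"Homo_sapiens"}, "strict")
        calls = apply_population_filter(calls, variants)
        all_calls += calls
        for c in calls:
            if c.population_pass:
                recovered.add((c.gene, c.column))

    # plant a common variant on one recovered site: it must now fail
    probe_gene, probe_col = sorted(planted)[0]
    spiked = pd.concat(
        [
            variants,
            pd.DataFrame(
                [
                    {
                        "gene": probe_gene,
                        "position": probe_col,
                        "ref_aa": "A",
                        "alt_aa": "V",
                        "allele_frequency": 0.2,
                        "disease_flag": False,
                    }
                ]
            ),
        ],
        ignore_index=True,
    )
    refiltered = apply_population_filter(list(all_calls), spiked)
    excluded = any(
        c.gene == probe_gene and c.column == probe_col and not c.population_pass
        for c in refiltered
    )
    n_recovered = len(planted & recovered)
    return PlantedScanResult(
        n_planted=len(planted),
        n_recovered=n_recovered,
        sensitivity=n_recovered / len(planted) if planted else float("nan"),
        common_variant_excluded=excluded,
    )
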