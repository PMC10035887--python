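import numpy as np
import pandas as pd
import pytest

from ligevo.annotation import CLASS_BINDING, annotate_orthogroup
from ligevo.sitemetrics import classify_variability
from ligevo.synthetic import (
    SimulationConfig,
    generate_binding_profiles,
    generate_dataset,
    generate_go_annotations,
    generate_population_variants,
    simulate_orthogroup,
    write_dataset,
)


class TestDeterminism:
    def test_profiles_byte_identical(self):
        a = generate_binding_profiles(5, seed=1).to_csv(sep="\t")
        b = generate_binding_profiles(5, seed=1).to_csv(sep="\t")
        assert a == b

    def test_whole_dataset_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_orthogroups=2, seq_length_range=(60, 90), seed=9)
        for name in ("run1", "run2"):
            write_dataset(generate_dataset(cfg, n_domains=8), tmp_path / name)
        for rel in [
            "binding_profiles.tsv", "domain_matches.tsv", "ground_truth.tsv",
            "variants.tsv", "go_annotations.tsv", "tree.nwk", "msa/OG0000.fasta",
        ]:
            assert (tmp_path / "run1" / rel).read_bytes() == (
                tmp_path / "run2" / rel
            ).read_bytes(), rel

    def test_go_annotations_deterministic(self):
        a = generate_go_annotations(["g1", "g2", "g3"], seed=2).to_csv()
        b = generate_go_annotations(["g1", "g2", "g3"], seed=2).to_csv()
        assert a == b


class TestBindingProfiles:
    def test_values_in_bounds(self, profiles):
        assert profiles["binding_frequency"].between(0, 1).all()
        assert profiles["cv_precision"].between(0, 1).all()
        # match states contiguous from 1 per (domain, ligand)
        for (_, _), sub in profiles.groupby(["domain_id", "ligand_type"]):
            ms = sorted(sub["match_state"])
            assert ms == list(range(1, len(ms) + 1))

    def test_all_zero_frequencies_give_no_binding_sites(self, reference_tree):
        prof = generate_binding_profiles(4, seed=3, p_binding=0.0, p_nonbinding=1.0)
        assert (prof["binding_frequency"] == 0).all()
        cfg = SimulationConfig(n_orthogroups=1, seq_length_range=(150, 150), seed=3)
        og, matches, truth = simulate_orthogroup(reference_tree, prof, cfg, seed=3)
        assert (truth["class"] != CLASS_BINDING).all()

    def test_binding_fraction_near_target(self):
        # precision 0.9 clears every threshold; binding states should be ~20%
        rng_prof = generate_binding_profiles(30, seed=4, p_binding=0.2, p_nonbinding=0.6)
        non_ion = rng_prof[rng_prof["ligand_type"] != "ion"]
        frac = (non_ion["binding_frequency"] >= 0.10).mean()
        n = len(non_ion)
        assert abs(frac - 0.2) < 3 * np.sqrt(0.2 * 0.8 / n)


class TestSimulateOrthogroup:
    def test_null_multiplier_equalises_rates(self, reference_tree, profiles):
        cfg = SimulationConfig(
            n_orthogroups=1, seq_length_range=(500, 500),
            rate_multiplier_binding=1.0, seed=5,
        )
        _, _, truth = simulate_orthogroup(reference_tree, profiles, cfg, seed=5)
        binding = truth.loc[truth["class"] == CLASS_BINDING, "true_rate"]
        other = truth.loc[truth["class"] != CLASS_BINDING, "true_rate"]
        # same gamma(1) distribution: means within sampling error
        se = np.sqrt(1 / len(binding) + 1 / len(other))
        assert abs(binding.mean() - other.mean()) < 3 * se

    def test_zero_multiplier_freezes_binding_columns(self, reference_tree, profiles):
        cfg = SimulationConfig(
            n_orthogroups=1, seq_length_range=(300, 300),
            rate_multiplier_binding=0.0, n_planted_human_specific=2, seed=6,
        )
        og, _, truth = simulate_orthogroup(reference_tree, profiles, cfg, seed=6)
        binding = truth[truth["class"] == CLASS_BINDING]
        assert len(binding)
        for _, row in binding.iterrows():
            state = classify_variability(og.column(int(row["column"])))
            expected = "variable" if row["planted_human_specific"] else "conserved"
            assert state == expected

    def test_half_multiplier_scales_mean_rate(self, reference_tree, profiles):
        cfg = SimulationConfig(
            n_orthogroups=1, seq_length_range=(500, 500),
            rate_multiplier_binding=0.5, seed=8,
        )
        _, _, truth = simulate_orthogroup(reference_tree, profiles, cfg, seed=8)
        binding = truth.loc[truth["class"] == CLASS_BINDING, "true_rate"]
        other = truth.loc[truth["class"] != CLASS_BINDING, "true_rate"]
        assert binding.mean() / other.mean() == pytest.approx(0.5, rel=0.25)

    def test_planted_sites_use_absent_residue(self, small_dataset):
        truth = small_dataset.ground_truth
        by_id = {og.orthogroup_id: og for og in small_dataset.orthogroups}
        planted = truth[truth["planted_human_specific"]]
        assert len(planted) == len(small_dataset.orthogroups)
        for row in planted.itertuples(index=False):
            og = by_id[row.orthogroup]
            column = og.column(int(row.column))
            human = column.pop("Homo_sapiens")
            assert human not in column.values()
            assert len(set(column.values())) == 1  # background monomorphic

    def test_excess_planting_request_rejected(self, reference_tree, profiles):
        cfg = SimulationConfig(
            n_orthogroups=1, seq_length_range=(60, 60),
            n_planted_human_specific=10_000, seed=1,
        )
        with pytest.raises(ValueError, match="planted"):
            simulate_orthogroup(reference_tree, profiles, cfg, seed=1)

    def test_annotation_matches_ground_truth_classes(self, small_dataset):
        # transferring annotations back onto the simulated orthogroup
        # reproduces the classes the generator recorded
        og = small_dataset.orthogroups[0]
        ann = annotate_orthogroup(og, small_dataset.matches, small_dataset.profiles)
        truth = small_dataset.ground_truth
        truth_og = truth[truth["orthogroup"] == og.orthogroup_id]
        assert list(ann["class"]) == list(truth_og["class"])


class TestVariants:
    def test_empty_orthogroup_list(self):
        cfg = SimulationConfig(seed=0)
        empty_truth = pd.DataFrame(
            columns=["gene", "orthogroup", "column", "true_rate", "class",
                     "ligand_types", "planted_human_specific"]
        )
        out = generate_population_variants([], empty_truth, cfg, seed=0)
        assert len(out) == 0
        assert list(out.columns) == [
            "gene", "position", "ref_aa", "alt_aa", "allele_frequency", "disease_flag"
        ]

    def test_common_fraction_near_mix(self, small_dataset):
        cfg = SimulationConfig(variant_maf_mix=(0.5, 0.10, 0.0), seed=2)
        out = generate_population_variants(
            small_dataset.orthogroups, small_dataset.ground_truth, cfg, seed=2
        )
        frac_common = (out["allele_frequency"] > 0.01).mean()
        n = len(out)
        assert abs(frac_common - 0.10) < 3 * np.sqrt(0.1 * 0.9 / n) + 0.01

    def test_all_common_variants_possible(self, small_dataset):
        # p_variant=1, p_common=1: every position carries a common variant
        cfg = SimulationConfig(variant_maf_mix=(1.0, 1.0, 0.0), seed=2)
        ds_no_plant = [og for og in small_dataset.orthogroups]
        truth = small_dataset.ground_truth.assign(planted_human_specific=False)
        out = generate_population_variants(ds_no_plant, truth, cfg, seed=2)
        assert (out["allele_frequency"] > 0.01).all()

    def test_planted_sites_only_rare_benign(self, small_dataset):
        truth = small_dataset.ground_truth
        planted = {
            (r.gene, int(r.column))
            for r in truth.itertuples(index=False)
            if r.planted_human_specific
        }
        v = small_dataset.variants
        for row in v.itertuples(index=False):
            if (row.gene, int(row.position)) in planted:
                assert row.allele_frequency <= 0.01
                assert not row.disease_flag
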