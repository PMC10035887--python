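import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ligevo.stats import (
    conover_posthoc,
    conservation_table,
    conserved_variable_2x2,
    fisher_exact_2x2,
    kruskal_wallis,
    ligand_rate_groups,
    mann_whitney_u,
)
from oracles import conover_iman_reference, fisher_enumeration


def _site_table(rows):
    return pd.DataFrame(
        rows, columns=["gene", "class", "ligand_types", "variable", "normalized_rate"]
    )


class TestConservationTable:
    def test_percent_and_counts(self):
        rows = [("g", "ligand_binding", "DNA", i >= 9, 1.0) for i in range(10)]
        rows += [("g", "other_within_domain", "", False, 1.0)] * 4
        rows += [("g", "other_outside_domain", "", True, 1.0)] * 2
        summary = conservation_table(_site_table(rows))
        assert summary.loc["ligand_binding", "n_sites"] == 10
        assert summary.loc["ligand_binding", "percent_conserved"] == pytest.approx(90.0)
        # 'other' pools inside- and outside-domain non-binding sites
        assert summary.loc["other", "n_sites"] == 6
        assert summary.loc["other_within_domain", "n_sites"] == 4

    def test_multi_ligand_site_counts_once_per_class(self):
        rows = [("g", "ligand_binding", "DNA,ion", False, 1.0)]
        summary = conservation_table(_site_table(rows))
        assert summary.loc["DNA", "n_sites"] == 1
        assert summary.loc["ion", "n_sites"] == 1
        assert summary.loc["ligand_binding", "n_sites"] == 1

    def test_additive_over_partitions(self, small_dataset):
        # summing summaries over disjoint orthogroup subsets = global summary
        truth = small_dataset.ground_truth.rename(columns={"true_rate": "normalized_rate"})
        truth = truth.assign(
            variable=np.tile([True, False], len(truth))[: len(truth)]
        )
        half = truth["gene"].isin(truth["gene"].unique()[:2])
        total = conservation_table(truth)
        parts = conservation_table(truth[half]) , conservation_table(truth[~half])
        summed = parts[0][["n_sites", "n_conserved"]].add(parts[1][["n_sites", "n_conserved"]])
        pd.testing.assert_frame_equal(total[["n_sites", "n_conserved"]], summed)


class TestFisher:
    def test_no_association(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [[[3, 1], [1, 3]], [[10, 2], [4, 9]], [[0, 7], [5, 2]], [[12, 0], [0, 9]]],
    )
    def test_matches_enumeration_oracle(self, table):
        assert fisher_exact_2x2(table) == pytest.approx(
            fisher_enumeration(table), rel=1e-12
        )

    @given(
        st.lists(st.integers(min_value=0, max_value=40), min_size=4, max_size=4).filter(
            lambda v: (v[0] + v[1]) and (v[2] + v[3]) and (v[0] + v[2]) and (v[1] + v[3])
        )
    )
    @settings(deadline=None, max_examples=100)
    def test_matches_scipy_and_symmetries(self, flat):
        t = np.array(flat).reshape(2, 2)
        p = fisher_exact_2x2(t)
        assert p == pytest.approx(sps.fisher_exact(t)[1], rel=1e-9)
        assert fisher_exact_2x2(t.T) == pytest.approx(p, rel=1e-9)
        assert fisher_exact_2x2(t[::-1, ::-1]) == pytest.approx(p, rel=1e-9)

    def test_large_counts_do_not_overflow(self):
        # counts at the scale of genome-wide site tables
        p = fisher_exact_2x2([[2_000_000, 500_000], [60_000, 7_000]])
        assert 0.0 <= p <= 1e-100  # hugely significant association

    def test_zero_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0


class TestMannWhitney:
    def test_identical_samples(self):
        assert mann_whitney_u([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_tiny_exact_enumeration(self):
        # all C(4,2)=6 rank splits; the observed extreme split has p=2/6
        assert mann_whitney_u([1, 2], [3, 4]) == pytest.approx(2 / 6)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(42)
        rejections = sum(
            mann_whitney_u(rng.normal(size=500), rng.normal(size=500)) < 0.05
            for _ in range(200)
        )
        # binomial 3-sigma band around 0.05 at 200 replicates
        assert 0.05 - 3 * 0.0154 <= rejections / 200 <= 0.05 + 3 * 0.0154

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis([[1, 1, 1], [1, 1], [1, 1, 1, 1]])
        assert h == 0.0 and p == 1.0

    def test_hand_computed_h(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        h, p = kruskal_wallis(groups)
        # no ties: H = 12/(N(N+1)) * sum(R_i^2/n_i) - 3(N+1)
        ranks = [6, 15, 24]
        expected = 12 / (9 * 10) * sum(r**2 / 3 for r in ranks) - 3 * 10
        assert h == pytest.approx(expected)
        assert p == pytest.approx(1 - sps.chi2.cdf(expected, df=2))

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(200):
            groups = [rng.normal(size=80) for _ in range(4)]
            rejections += kruskal_wallis(groups)[1] < 0.05
        assert 0.05 - 3 * 0.0154 <= rejections / 200 <= 0.05 + 3 * 0.0154

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestConover:
    def test_identical_groups_all_p_one(self):
        groups = {c: [2.0, 2.0, 2.0] for c in "ABCDE"}
        out = conover_posthoc(groups)
        assert len(out) == 10
        assert (out["adj_p"] == 1.0).all()

    def test_separated_groups_significant_with_direction(self):
        groups = {
            "slow": [1.0, 1.1, 1.2, 1.3, 0.9],
            "mid": [5.0, 5.2, 4.8, 5.1, 5.3],
            "fast": [9.0, 9.5, 8.8, 9.2, 9.1],
        }
        out = conover_posthoc(groups).set_index(["ligand_a", "ligand_b"])
        assert (out["adj_p"] < 0.05).all()
        assert out.loc[("slow", "fast"), "direction"] == "b_faster"
        assert out.loc[("mid", "fast"), "direction"] == "b_faster"
        assert out.loc[("slow", "mid"), "direction"] == "b_faster"

    def test_matches_independent_reference(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            sizes = rng.integers(8, 30, size=4)
            groups = [rng.normal(loc=rng.normal(), size=n) for n in sizes]
            # inject ties to exercise the tie correction
            groups[0][:3] = groups[1][:3]
            out = conover_posthoc({str(i): g for i, g in enumerate(groups)})
            ref = conover_iman_reference(groups)
            for row in out.itertuples(index=False):
                raw_ref, adj_ref = ref[(int(row.ligand_a), int(row.ligand_b))]
                assert abs(row.raw_p - raw_ref) < 1e-8
                assert abs(row.adj_p - adj_ref) < 1e-8

    def test_small_group_not_testable(self):
        out = conover_posthoc({"a": [1.0], "b": [2.0, 3.0, 4.0]})
        assert np.isnan(out.loc[0, "raw_p"])


class TestHelpers:
    def test_conserved_variable_2x2(self):
        summary = pd.DataFrame(
            {"n_sites": [100, 50], "n_conserved": [90, 30]},
            index=["ligand_binding", "other"],
        )
        table = conserved_variable_2x2(summary, "ligand_binding", "other")
        np.testing.assert_array_equal(table, [[90, 10], [30, 20]])

    def test_ligand_rate_groups_multi_membership(self):
        t = pd.DataFrame(
            {
                "class": ["ligand_binding", "ligand_binding", "other_within_domain"],
                "ligand_types": ["DNA,ion", "DNA", ""],
                "normalized_rate": [0.5, 0.8, 1.2],
            }
        )
        groups = ligand_rate_groups(t)
        np.testing.assert_allclose(groups["DNA"], [0.5, 0.8])
        np.testing.assert_allclose(groups["ion"], [0.5])
        assert "peptide" not in groups
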