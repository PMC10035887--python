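import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ligevo.phylo import PrimatePhylogeny
from ligevo.sitemetrics import (
    RATE_LOWER,
    RATE_UPPER,
    SiteRateModel,
    classify_variability,
    column_entropy,
    estimate_site_rate,
    normalize_rates,
    site_log_likelihood,
)
from oracles import four_leaf_enumeration_loglik


class TestEntropy:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ("A" * 18, 0.0),
            ("A" * 9 + "V" * 9, math.log(2)),
            ("A" * 17 + "V", -(17 / 18 * math.log(17 / 18) + 1 / 18 * math.log(1 / 18))),
            ("K" * 10 + "-" * 5, 0.0),  # gaps excluded from frequencies
        ],
    )
    def test_known_values(self, column, expected):
        assert column_entropy(column) == pytest.approx(expected, abs=1e-12)

    def test_all_gap_column_is_missing(self):
        assert math.isnan(column_entropy("---"))
        assert classify_variability("---") is None

    @given(
        st.lists(
            st.sampled_from("ACDVKR-"), min_size=1, max_size=18
        ).filter(lambda c: any(x != "-" for x in c))
    )
    @settings(deadline=None, max_examples=200)
    def test_zero_entropy_iff_conserved(self, column):
        h = column_entropy(column)
        conserved = classify_variability(column) == "conserved"
        assert (h == pytest.approx(0.0, abs=1e-12)) == conserved


class TestVariability:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ("K" * 15, "conserved"),
            ("K" * 14 + "R", "variable"),
            ("K" * 10 + "-" * 5, "conserved"),
        ],
    )
    def test_rule(self, column, expected):
        assert classify_variability(column) == expected


class TestLikelihood:
    def test_single_leaf_is_stationary_frequency(self, jtt_model):
        tree = PrimatePhylogeny.from_newick("(A:0.5);")
        ll = site_log_likelihood({"A": "W"}, tree, jtt_model, rate=1.0)
        from ligevo.substitution import AA_INDEX

        assert ll == pytest.approx(math.log(jtt_model.pi[AA_INDEX["W"]]), abs=1e-10)

    def test_two_leaf_closed_form_by_reversibility(self, jtt_model):
        t1, t2, r = 0.2, 0.45, 0.8
        tree = PrimatePhylogeny.from_newick(f"(A:{t1},B:{t2});")
        ll = site_log_likelihood({"A": "K", "B": "E"}, tree, jtt_model, rate=r)
        from ligevo.substitution import AA_INDEX

        a, b = AA_INDEX["K"], AA_INDEX["E"]
        p = jtt_model.transition_matrices(np.array(r * (t1 + t2)))
        closed = math.log(jtt_model.pi[a] * p[a, b])
        assert ll == pytest.approx(closed, abs=1e-10)

    @pytest.mark.parametrize(
        "residues, rate",
        [
            (("A", "A", "A", "A"), 0.5),
            (("K", "R", "K", "E"), 1.0),
            (("W", "C", "H", "P"), 0.2),
            (("L", "L", "V", "I"), 3.0),
        ],
    )
    def test_pruning_equals_state_enumeration(self, four_leaf_tree, jtt_model, residues, rate):
        lengths = (0.12, 0.27, 0.33, 0.08, 0.05, 0.19)
        column = dict(zip("ABCD", residues))
        ll = site_log_likelihood(column, four_leaf_tree, jtt_model, rate)
        oracle = four_leaf_enumeration_loglik(residues, lengths, jtt_model, rate)
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_gap_leaf_equals_pruned_tree(self, jtt_model):
        # a gapped leaf (uniform partials) is equivalent to removing it
        full = PrimatePhylogeny.from_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        ll_gap = site_log_likelihood({"A": "K", "B": "R", "C": "-"}, full, jtt_model, 1.0)
        pruned = PrimatePhylogeny.from_newick("(A:0.1,B:0.2);")
        ll_pruned = site_log_likelihood({"A": "K", "B": "R"}, pruned, jtt_model, 1.0)
        assert ll_gap == pytest.approx(ll_pruned, abs=1e-10)

    def test_invalid_inputs(self, four_leaf_tree, jtt_model):
        with pytest.raises(ValueError, match="positive"):
            site_log_likelihood({"A": "K"}, four_leaf_tree, jtt_model, rate=0.0)
        with pytest.raises(ValueError, match="not in tree"):
            site_log_likelihood({"Z": "K"}, four_leaf_tree, jtt_model, rate=1.0)
        with pytest.raises(ValueError, match="no non-gap"):
            site_log_likelihood({"A": "-"}, four_leaf_tree, jtt_model, rate=1.0)


class TestRateEstimation:
    def test_invariant_column_at_lower_bound(self, four_leaf_tree):
        column = {"A": "G", "B": "G", "C": "G", "D": "G"}
        assert estimate_site_rate(column, four_leaf_tree) == RATE_LOWER

    def test_saturated_column_near_upper_bound(self, four_leaf_tree):
        column = {"A": "A", "B": "W", "C": "H", "D": "P"}
        r = estimate_site_rate(column, four_leaf_tree)
        assert r > RATE_UPPER / 4

    def test_matches_dense_grid_oracle(self, jtt_model):
        # six-leaf tree; dense-grid maximiser within 1e-3 of the estimate
        tree = PrimatePhylogeny.from_newick(
            "(((A:0.1,B:0.15):0.05,(C:0.2,D:0.1):0.1):0.05,(E:0.3,F:0.25):0.05);"
        )
        rng = np.random.default_rng(5)
        aas = "ARNDCQEGHILKMFPSTWYV"
        coarse = np.geomspace(RATE_LOWER, RATE_UPPER, 10_000)

        def grid_max(column, grid):
            ll = [site_log_likelihood(column, tree, jtt_model, r) for r in grid]
            return int(np.argmax(ll))

        for _ in range(6):
            column = {sp: aas[rng.integers(20)] for sp in "ABCDEF"}
            if len(set(column.values())) < 2:
                continue
            k = grid_max(column, coarse)
            # second brute-force pass resolves the maximiser below 1e-5
            fine = np.linspace(
                coarse[max(k - 1, 0)], coarse[min(k + 1, coarse.size - 1)], 10_000
            )
            oracle = fine[grid_max(column, fine)]
            est = estimate_site_rate(column, tree, jtt_model)
            assert est == pytest.approx(oracle, abs=1e-3)

    def test_more_mismatches_never_slower(self, jtt_model):
        # star-like tree: adding mismatching leaves increases the estimate
        tree = PrimatePhylogeny.from_newick(
            "(((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05):0.02,(E:0.1,F:0.1):0.07);"
        )
        columns = [
            dict(zip("ABCDEF", "AAAAAA")),
            dict(zip("ABCDEF", "AAAAAV")),
            dict(zip("ABCDEF", "AAAVAV")),
            dict(zip("ABCDEF", "AVAVAV")),
        ]
        rates = [estimate_site_rate(c, tree, jtt_model) for c in columns]
        assert all(r2 >= r1 for r1, r2 in zip(rates, rates[1:]))


class TestNormalization:
    @pytest.mark.parametrize(
        "rates, expected",
        [([2.0, 2.0, 2.0], [1.0, 1.0, 1.0]), ([1.0, 3.0], [0.5, 1.5])],
    )
    def test_known_values(self, rates, expected):
        np.testing.assert_allclose(normalize_rates(rates), expected)

    @given(
        st.lists(st.floats(min_value=1e-4, max_value=20.0), min_size=1, max_size=50)
    )
    @settings(deadline=None, max_examples=100)
    def test_output_mean_is_one(self, rates):
        assert normalize_rates(rates).mean() == pytest.approx(1.0, abs=1e-12)

    def test_all_invariant_orthogroup_flattened(self):
        out = normalize_rates([RATE_LOWER] * 4)
        np.testing.assert_allclose(out, 1.0)


class TestSiteRateModel:
    def test_fit_results_consistency(self, reference_tree, small_dataset):
        og = small_dataset.orthogroups[0]
        results = SiteRateModel(og, reference_tree).fit()
        frame = results.frame
        assert len(frame) == og.n_columns
        # normalisation holds over the fitted orthogroup
        assert frame["normalized_rate"].mean() == pytest.approx(1.0, abs=1e-9)
        # entropy zero exactly on non-variable scored columns
        scored = frame[frame["n_effective"] > 0]
        conserved = scored[~scored["variable"].astype(bool)]
        assert (conserved["entropy"].abs() < 1e-12).all()
        assert (conserved["ml_rate"] == RATE_LOWER).all()
        text = results.summary()
        assert "Substitution model:  JTT" in text
        assert og.orthogroup_id in text
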