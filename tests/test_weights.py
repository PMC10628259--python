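"""Feature weighting: ensembles, win-win layers, balancing, distinctiveness."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conplan.core import SuitabilityStack
from conplan.weights import (ensemble_average, endemism_weight,
                             fair_proportion_ed, functional_distinctiveness,
                             gower_distance, kingdom_balance, scenario_weights,
                             subset_by_status, winwin_combine)


def stack(arrays, ids=None):
    arrays = np.asarray(arrays, float)
    ids = ids or [f"s{i}" for i in range(arrays.shape[0])]
    return SuitabilityStack(arrays, ids)


class TestEnsembleAverage:
    def test_identical_inputs_returned_unchanged(self):
        a = np.random.default_rng(0).random((5, 5))
        assert np.allclose(ensemble_average(a, a), a)

    def test_default_weights_blend_ones_and_zeros_to_070(self):
        out = ensemble_average(np.ones((3, 3)), np.zeros((3, 3)))
        assert np.allclose(out, 0.7)

    def test_matches_cellwise_formula(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((4, 6)), rng.random((4, 6))
        out = ensemble_average(a, b, (0.6, 0.4))
        assert np.allclose(out, 0.6 * a + 0.4 * b)

    def test_rejects_misaligned_or_bad_weights(self):
        with pytest.raises(ValueError):
            ensemble_average(np.ones((2, 2)), np.ones((3, 3)))
        with pytest.raises(ValueError):
            ensemble_average(np.ones((2, 2)), np.ones((2, 2)), (0.7, 0.7))


class TestWinWin:
    def test_cell_type_ordering_after_rescale(self):
        """both-cell > current-only > future-only > 0 at equal suitability;
        with defaults (0.5, 0.35, 0.15) and s=1 the saturated both-cell
        rescales to 1, current-only to 0.35, future-only to 0.15."""
        cur = stack([[[1.0, 1.0, 0.0]]])
        fut = stack([[[1.0, 0.0, 1.0]]])
        layer = winwin_combine(cur, fut).stack.values[0, 0]
        assert np.allclose(layer, [1.0, 0.35, 0.15])
        assert layer[0] > layer[1] > layer[2] > 0

    def test_overlap_saturates_the_formula(self):
        s = 0.6
        cur = stack([[[s, s]]])
        out = winwin_combine(cur, cur).stack.values
        assert np.allclose(out, 1.0)  # equal cells all rescale to max

    def test_zero_where_both_time_slices_zero(self):
        rng = np.random.default_rng(2)
        cur = stack(rng.random((3, 5, 5)) * (rng.random((3, 5, 5)) > 0.5))
        fut = stack(rng.random((3, 5, 5)) * (rng.random((3, 5, 5)) > 0.5))
        out = winwin_combine(cur, fut).stack.values
        both_zero = (cur.values == 0) & (fut.values == 0)
        assert (out[both_zero] == 0).all()

    def test_monotone_in_current_suitability(self):
        rng = np.random.default_rng(3)
        cur = rng.random((1, 4, 4))
        fut = rng.random((1, 4, 4))
        base = winwin_combine(stack(cur), stack(fut)).stack.values[0, 1, 2]
        cur2 = cur.copy()
        cur2[0, 1, 2] = min(1.0, cur2[0, 1, 2] + 0.3)
        bumped = winwin_combine(stack(cur2), stack(fut)).stack.values[0, 1, 2]
        assert bumped >= base - 1e-12

    def test_coefficient_ordering_enforced(self):
        cur = stack([[[1.0]]])
        with pytest.raises(ValueError):
            winwin_combine(cur, cur, (0.3, 0.35, 0.15))


class TestKingdomBalance:
    def test_equal_totals_proportional_rescale(self):
        table = pd.DataFrame({
            "species_id": list("abcdef"),
            "kingdom": ["vertebrate"] * 2 + ["plant"] * 4,
            "weight": 1.0,
        })
        out = kingdom_balance(table, {"vertebrate": 1.0, "plant": 1.0})
        assert np.allclose(out[out.kingdom == "vertebrate"]["weight"], 0.5)
        assert np.allclose(out[out.kingdom == "plant"]["weight"], 0.25)

    def test_single_kingdom_is_normalization(self):
        table = pd.DataFrame({"species_id": list("abc"),
                              "kingdom": "plant", "weight": [2.0, 1.0, 1.0]})
        out = kingdom_balance(table)
        assert np.isclose(out["weight"].sum(), 1.0)

    def test_within_kingdom_ratios_preserved(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame({
            "species_id": [f"s{i}" for i in range(10)],
            "kingdom": ["plant"] * 6 + ["butterfly"] * 4,
            "weight": rng.random(10) + 0.1,
        })
        out = kingdom_balance(table)
        for k in ("plant", "butterfly"):
            raw = table[table.kingdom == k]["weight"].to_numpy()
            new = out[out.kingdom == k]["weight"].to_numpy()
            assert np.allclose(new / new.sum(), raw / raw.sum())
        sums = out.groupby("kingdom")["weight"].sum()
        assert np.allclose(sums, sums.iloc[0])

    def test_all_zero_kingdom_rejected(self):
        table = pd.DataFrame({"species_id": ["a", "b"],
                              "kingdom": ["plant", "plant"], "weight": 0.0})
        with pytest.raises(ValueError):
            kingdom_balance(table)


class TestSubsetByStatus:
    @pytest.fixture
    def table(self):
        return pd.DataFrame({
            "species_id": list("abcdef"),
            "kingdom": ["vertebrate"] * 3 + ["plant"] * 3,
            "status_national": ["threatened", "not_at_risk", "endangered",
                                "special_concern", "not_at_risk", "not_at_risk"],
            "status_global": ["least_concern", "vulnerable", "endangered",
                              "least_concern", "least_concern", "critically_endangered"],
            "weight": 1.0,
        })

    def test_membership_equals_set_filter(self, table):
        out = subset_by_status(table, "national")
        assert sorted(out["species_id"]) == ["a", "c", "d"]

    def test_national_and_global_schemes_differ(self, table):
        nat = set(subset_by_status(table, "national")["species_id"])
        glob = set(subset_by_status(table, "global")["species_id"])
        assert nat == {"a", "c", "d"} and glob == {"b", "c", "f"}
        assert nat != glob

    def test_weights_rebalanced_across_remaining_kingdoms(self, table):
        out = subset_by_status(table, "national")
        sums = out.groupby("kingdom")["weight"].sum()
        assert np.allclose(sums, sums.iloc[0])

    def test_no_species_at_risk_is_an_error(self, table):
        table["status_national"] = "not_at_risk"
        with pytest.raises(ValueError):
            subset_by_status(table, "national")


class TestFairProportion:
    def tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick",
                                 rooting="force-rooted",
                                 preserve_underscores=True)

    def test_hand_worked_three_tip_tree(self):
        ed = fair_proportion_ed(self.tree("((A:1,B:1):1,C:2);"))
        assert ed["A"] == pytest.approx(1.5)
        assert ed["B"] == pytest.approx(1.5)
        assert ed["C"] == pytest.approx(2.0)

    def test_star_tree_symmetry(self):
        ed = fair_proportion_ed(self.tree("(A:2,B:2,C:2,D:2);"))
        assert np.allclose(ed, 2.0)

    def test_scores_sum_to_total_tree_length(self):
        t = self.tree("(((A:0.3,B:0.7):0.2,C:1.1):0.4,(D:0.6,E:0.6):0.9);")
        ed = fair_proportion_ed(t)
        assert ed.sum() == pytest.approx(t.length(), rel=1e-12)

    def test_duplicate_labels_rejected(self):
        t = self.tree("((A:1,B:1):1,C:2);")
        for leaf in t.leaf_node_iter():
            if leaf.taxon.label == "B":
                leaf.taxon.label = "A"
        with pytest.raises(ValueError):
            fair_proportion_ed(t)


class TestFunctionalDistinctiveness:
    def test_square_corners_get_equal_quarter_contributions(self):
        traits = pd.DataFrame({"t1": [0.0, 0.0, 1.0, 1.0],
                               "t2": [0.0, 1.0, 0.0, 1.0]},
                              index=list("abcd"))
        fd = functional_distinctiveness(traits)
        assert np.allclose(fd, 0.25)

    def test_extreme_species_has_largest_contribution(self):
        traits = pd.DataFrame({"t1": [0.0, 0.1, 0.05, 0.12, 5.0],
                               "t2": [0.1, 0.0, 0.12, 0.05, 5.0]},
                              index=list("abcde"))
        fd = functional_distinctiveness(traits)
        assert fd.idxmax() == "e"

    def test_contributions_sum_to_one_per_kingdom(self):
        rng = np.random.default_rng(5)
        traits = pd.DataFrame({
            "num": rng.random(12),
            "cat": rng.choice(["x", "y"], 12),
        }, index=[f"s{i}" for i in range(12)])
        kingdom = pd.Series(["plant"] * 6 + ["vertebrate"] * 6, index=traits.index)
        fd = functional_distinctiveness(traits, kingdom)
        assert fd.groupby(kingdom).sum().round(12).eq(1.0).all()
        assert (fd >= 0).all()

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(6)
        traits = pd.DataFrame({"a": rng.random(8), "b": rng.random(8)},
                              index=[f"s{i}" for i in range(8)])
        fd = functional_distinctiveness(traits)
        perm = traits.sample(frac=1, random_state=1)
        fd_perm = functional_distinctiveness(perm)
        pd.testing.assert_series_equal(fd.sort_index(), fd_perm.sort_index())

    def test_all_constant_traits_rejected(self):
        traits = pd.DataFrame({"a": [1.0] * 4}, index=list("abcd"))
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                functional_distinctiveness(traits)

    def test_gower_handles_mixed_types(self):
        traits = pd.DataFrame({"num": [0.0, 1.0], "cat": ["x", "y"]})
        d = gower_distance(traits)
        assert d[0, 1] == pytest.approx(1.0)
        assert d[0, 0] == 0.0


class TestEndemism:
    def test_fully_endemic_species_scores_one(self):
        focal = stack([np.ones((3, 3))])
        assert endemism_weight(focal, focal).iloc[0] == pytest.approx(1.0)

    def test_uniform_range_twice_the_focal_area_scores_half(self):
        focal = stack([np.full((3, 3), 0.4)])
        total = stack([np.full((3, 6), 0.4)])
        assert endemism_weight(focal, total).iloc[0] == pytest.approx(0.5)

    def test_matches_ratio_of_sums_oracle(self):
        rng = np.random.default_rng(7)
        focal_vals = rng.random((4, 3, 3))
        extra = rng.random((4, 3, 3))
        total_vals = np.concatenate([focal_vals, extra], axis=2)
        share = endemism_weight(stack(focal_vals), stack(total_vals))
        expected = focal_vals.reshape(4, -1).sum(1) / total_vals.reshape(4, -1).sum(1)
        assert np.allclose(share, expected)

    def test_zero_total_range_rejected(self):
        focal = stack([np.zeros((2, 2))])
        with pytest.raises(ValueError):
            endemism_weight(focal, focal)


@given(seed=st.integers(0, 100))
@settings(max_examples=25, deadline=None)
def test_scenario_weight_tables_satisfy_kingdom_sum_invariant(seed):
    rng = np.random.default_rng(seed)
    n = 12
    table = pd.DataFrame({
        "species_id": [f"s{i}" for i in range(n)],
        "kingdom": rng.choice(["vertebrate", "plant", "butterfly"], n),
        "endemism_share": rng.random(n) * 0.9 + 0.1,
    })
    for source in ("uniform", "endemism"):
        try:
            out = scenario_weights(table, source)
        except ValueError:
            continue  # a kingdom may be absent for this draw
        sums = out.groupby("kingdom")["weight"].sum()
        assert np.allclose(sums, 1.0 / out["kingdom"].nunique())
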