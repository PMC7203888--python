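import math
import warnings
from fractions import Fraction
from itertools import permutations

import pytest
from hypothesis import given, settings

from labourpath import (
    DEFAULT_PROTOCOL,
    PathCountTable,
    estimate_progression_proportions,
    form1_decompose,
    order_sensitivity,
    overall_treatment_ratio,
    stepwise_replacement,
)
from labourpath.decompose import evaluate_functional, order_sensitivity_summary
from labourpath.markov import UndefinedProgressionWarning
from labourpath.measures import round_half_away

from conftest import path_count_tables


@pytest.fixture(scope="module")
def pps_pair(bcm, acm):
    return (
        estimate_progression_proportions(bcm),
        estimate_progression_proportions(acm),
    )


class TestForm1Decompose:
    def test_reference_cohorts(self, bcm, acm):
        d = form1_decompose(bcm, acm)
        assert d.rel_S == pytest.approx(-0.2477, abs=5e-4)  # S fell by ~25%
        assert d.rel_H_T == pytest.approx(-0.0352, abs=5e-4)  # H_T: -3.5%
        assert d.total == pytest.approx(-0.2742, abs=5e-4)  # overall: -27.4%
        assert d.total == pytest.approx(
            d.rel_S + d.rel_H_T + d.interaction, abs=1e-12
        )

    def test_identical_cohorts_all_zero(self, bcm):
        d = form1_decompose(bcm, bcm)
        assert d.rel_S == d.rel_H_T == d.interaction == d.total == 0

    def test_halving_s_with_ht_fixed(self, bcm):
        # doubling the untreated count halves S, leaves H_T unchanged
        counts = dict(bcm.counts)
        counts[(0, 0, 0)] = counts[(0, 0, 0)] + 637  # N doubles, treated fixed
        stretched = PathCountTable(DEFAULT_PROTOCOL, counts)
        d = form1_decompose(bcm, stretched)
        assert d.rel_H_T == 0
        assert d.total == pytest.approx(d.rel_S, abs=1e-12)

    def test_untreated_cohort_one_raises(self):
        t = PathCountTable(DEFAULT_PROTOCOL, {(0, 0, 0): 5})
        with pytest.raises(ValueError):
            form1_decompose(t, t)


# every printed cell of the published replacement grid, by functional:
# (step values incl. endpoints, partial differences, relative contributions)
REFERENCE_GRID = {
    "H": (
        [0.482, 0.347, 0.360, 0.358, 0.360, 0.351, 0.350],
        [-0.135, 0.013, -0.002, 0.002, -0.009, -0.001],
        [-100.00, 9.50, -1.60, 1.70, -6.48, -1.02],
    ),
    "C": (
        [0.102, 0.083, 0.083, 0.081, 0.081, 0.073, 0.071],
        [-0.020, 0.001, -0.002, 0.000, -0.009, -0.001],
        [-100.0, 4.5, -11.0, 0.8, -44.8, -7.0],
    ),
    "V+C": (
        [0.144, 0.116, 0.129, 0.127, 0.129, 0.121, 0.119],
        [-0.028, 0.013, -0.002, 0.002, -0.009, -0.001],
        [-100.0, 45.8, -7.7, 8.2, -31.3, -4.9],
    ),
}
CONTRIB_DECIMALS = {"H": 2, "C": 1, "V+C": 1}


class TestStepwiseReplacement:
    @pytest.mark.parametrize("functional", ["H", "C", "V+C"])
    def test_reference_grid_reproduced_after_rounding(self, pps_pair, functional):
        p1, p2 = pps_pair
        dec = stepwise_replacement(p1, p2, functional)
        values, deltas, contribs = REFERENCE_GRID[functional]
        assert [round_half_away(v, 3) for v in dec.step_values] == values
        assert [round_half_away(d, 3) for d in dec.deltas] == deltas
        nd = CONTRIB_DECIMALS[functional]
        assert [round_half_away(c, nd) for c in dec.contributions] == contribs

    def test_default_order_is_natural(self, pps_pair):
        dec = stepwise_replacement(*pps_pair)
        assert dec.order == (
            ("O", "A"), ("O", "V"), ("O", "C"),
            ("A", "V"), ("A", "C"), ("V", "C"),
        )

    def test_endpoints_match_cohort_functionals(self, pps_pair, bcm, acm):
        p1, p2 = pps_pair
        dec = stepwise_replacement(p1, p2, "H")
        assert dec.step_values[0] == pytest.approx(
            overall_treatment_ratio(bcm).H, abs=1e-12
        )
        assert dec.step_values[-1] == pytest.approx(
            overall_treatment_ratio(acm).H, abs=1e-12
        )
        assert sum(dec.deltas) == pytest.approx(dec.total, abs=1e-12)
        assert dec.contributions[0] == -100.0

    def test_identical_pps_all_deltas_zero(self, pps_pair):
        p1, _ = pps_pair
        dec = stepwise_replacement(p1, p1, "H")
        assert all(d == 0 for d in dec.deltas)
        assert dec.contributions is None  # first delta zero -> scale undefined

    def test_bad_order_rejected(self, pps_pair):
        p1, p2 = pps_pair
        with pytest.raises(ValueError):
            stepwise_replacement(p1, p2, "H", order=[("O", "A")])

    def test_unknown_functional_rejected(self, pps_pair):
        with pytest.raises(ValueError):
            stepwise_replacement(*pps_pair, functional="Z")


class TestOrderSensitivity:
    def test_additivity_across_all_720_orders(self, pps_pair, bcm, acm):
        p1, p2 = pps_pair
        total = overall_treatment_ratio(acm).H - overall_treatment_ratio(bcm).H
        detail = order_sensitivity(p1, p2, "H")
        assert detail["order"].nunique() == math.factorial(6)
        sums = detail.groupby("order")["partial_difference"].sum()
        assert (sums - total).abs().max() < 1e-12

    def test_augmentation_entry_dominates_shapley(self, pps_pair):
        summary = order_sensitivity_summary(order_sensitivity(*pps_pair, "H"))
        means = dict(zip(summary["pp"], summary["shapley_mean"].abs()))
        assert means["O->A"] == max(means.values())

    def test_single_differing_pp_is_order_invariant(self, pps_pair):
        p1, _ = pps_pair
        p2 = p1.replace("O", "A", Fraction(1, 5))
        detail = order_sensitivity(p1, p2, "H")
        oa = detail[detail["pp"] == "O->A"]["partial_difference"]
        assert oa.nunique() == 1
        rest = detail[detail["pp"] != "O->A"]["partial_difference"]
        assert (rest == 0).all()

    def test_cap_enforced_without_sample(self, pps_pair):
        p1, p2 = pps_pair
        with pytest.raises(ValueError):
            order_sensitivity(p1, p2, "H", max_orders=10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(t1=path_count_tables(n_max=3), t2=path_count_tables(n_max=3))
def test_stepwise_consistency_with_direct_difference(t1, t2):
    """For any pair of same-protocol cohorts and any order, the partial
    differences sum exactly to H2 - H1 as computed by the measures layer."""
    if t1.protocol.n != t2.protocol.n:
        return
    t2 = PathCountTable(t1.protocol, {p: c for p, c in t2.counts.items()})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UndefinedProgressionWarning)
        p1 = estimate_progression_proportions(t1)
        p2 = estimate_progression_proportions(t2)
        orders = list(permutations(p1.pairs()))
        order = orders[len(orders) // 2]  # an arbitrary non-default order
        dec = stepwise_replacement(p1, p2, "H", order)
        h1 = overall_treatment_ratio(t1).H_exact
        h2 = overall_treatment_ratio(t2).H_exact
        assert abs(sum(dec.deltas) - float(h2 - h1)) < 1e-12
        assert dec.step_values[0] == pytest.approx(float(h1), abs=1e-12)
        assert dec.step_values[-1] == pytest.approx(float(h2), abs=1e-12)
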