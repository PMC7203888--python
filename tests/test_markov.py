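import json
import warnings
from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from scipy.stats import hypergeom

from labourpath import (
    DEFAULT_PROTOCOL,
    InterventionProtocol,
    PathCountTable,
    estimate_progression_proportions,
    markov_property_test,
    otr_from_pps,
    reconstruct_path_distribution,
    visit_probabilities,
)
from labourpath.markov import ONSET, ProgressionProportions, UndefinedProgressionWarning

from conftest import path_count_tables


def brute_force_visit_probabilities(pps):
    """Oracle: sum path probabilities over an explicit enumeration of all
    2^n paths of the chain (independent of the forward recursion)."""
    labels = pps.protocol.labels
    n = len(labels)
    visit = {l: 0.0 for l in labels}
    for flags in product((0, 1), repeat=n):
        visited = [labels[i] for i in range(n) if flags[i]]
        prob, prev = 1.0, ONSET
        for t in visited:
            prob *= float(pps.get(prev, t))
            prev = t
        idx = pps.states.index(prev)
        prob *= 1.0 - sum(float(pps.get(prev, t)) for t in pps.states[idx + 1:])
        for t in visited:
            visit[t] += prob
    return visit


class TestEstimation:
    def test_reference_pps_match_published_decomposition_table(self, bcm, acm):
        pb = estimate_progression_proportions(bcm)
        got = {k: round(float(v), 3) for k, v in pb.pp.items()}
        assert got == {
            ("O", "A"): 0.338, ("O", "V"): 0.016, ("O", "C"): 0.039,
            ("A", "V"): 0.079, ("A", "C"): 0.177, ("V", "C"): 0.074,
        }
        pa = estimate_progression_proportions(acm)
        got = {k: round(float(v), 3) for k, v in pa.pp.items()}
        assert got == {
            ("O", "A"): 0.231, ("O", "V"): 0.028, ("O", "C"): 0.037,
            ("A", "V"): 0.088, ("A", "C"): 0.139, ("V", "C"): 0.045,
        }

    def test_pooling_across_arrival_routes(self, bcm):
        # p_VC pools direct (O->V) and via-A arrivals: 27 reach V, 2 progress
        pb = estimate_progression_proportions(bcm)
        assert pb.pp[("V", "C")] == Fraction(2, 27)
        assert pb.denominators["V"] == 27

    def test_untreated_cohort_all_zero_or_undefined(self):
        t = PathCountTable(DEFAULT_PROTOCOL, {(0, 0, 0): 50})
        pps = estimate_progression_proportions(t)
        assert all(pps.pp[("O", x)] == 0 for x in "AVC")
        assert ("A", "V") in pps.undefined and ("V", "C") in pps.undefined
        with pytest.warns(UndefinedProgressionWarning):
            assert pps.get("A", "V") == 0


class TestVisitProbabilities:
    def test_visit_probabilities_equal_type_specific_ratios(self, bcm):
        pps = estimate_progression_proportions(bcm)
        v = visit_probabilities(pps)
        assert v == {
            "A": Fraction(215, 637),
            "V": Fraction(27, 637),
            "C": Fraction(65, 637),
        }

    def test_integer_visit_identity(self, bcm, acm):
        """N·v_j equals the integer treatment count E_j exactly."""
        for table in (bcm, acm):
            pps = estimate_progression_proportions(table)
            for label, v in visit_probabilities(pps).items():
                prod = table.N * v
                assert prod.denominator == 1

    def test_zero_onset_pps_give_zero_vector(self):
        pps = ProgressionProportions(
            DEFAULT_PROTOCOL,
            {("O", "A"): 0.0, ("O", "V"): 0.0, ("O", "C"): 0.0,
             ("A", "V"): 0.5, ("A", "C"): 0.2, ("V", "C"): 0.3},
        )
        assert all(v == 0 for v in visit_probabilities(pps).values())

    def test_recursion_matches_enumeration_for_five_interventions(self):
        rng = np.random.default_rng(42)
        labels = tuple("PQRST")
        protocol = InterventionProtocol(labels)
        pp = {}
        states = [ONSET, *labels]
        for i, s in enumerate(states[:-1]):
            raw = rng.random(len(states) - 1 - i)
            raw = raw / max(1.0, raw.sum() * 1.1)
            for t, p in zip(states[i + 1:], raw):
                pp[(s, t)] = float(p)
        pps = ProgressionProportions(protocol, pp)
        v = visit_probabilities(pps)
        oracle = brute_force_visit_probabilities(pps)
        for l in labels:
            assert float(v[l]) == pytest.approx(oracle[l], abs=1e-12)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            ProgressionProportions(DEFAULT_PROTOCOL, {("O", "A"): 1.5})


class TestReconstruction:
    def test_distribution_sums_to_one(self, bcm):
        pps = estimate_progression_proportions(bcm)
        f = reconstruct_path_distribution(pps)
        assert sum(f.values()) == 1

    def test_markov_consistent_cohort_is_fixed_point(self):
        # cohort generated exactly by a chain: counts proportional to products
        pps = ProgressionProportions(
            DEFAULT_PROTOCOL,
            {("O", "A"): Fraction(1, 2), ("O", "V"): Fraction(1, 4),
             ("O", "C"): Fraction(0), ("A", "V"): Fraction(1, 2),
             ("A", "C"): Fraction(0), ("V", "C"): Fraction(1, 2)},
        )
        f = reconstruct_path_distribution(pps)
        scale = 16  # common denominator of all path probabilities
        counts = {p: int(prob * scale) for p, prob in f.items()}
        assert sum(counts.values()) == scale
        table = PathCountTable(DEFAULT_PROTOCOL, counts)
        refit = estimate_progression_proportions(table)
        f2 = reconstruct_path_distribution(refit)
        for p in f:
            assert f2[p] == f[p]

    def test_path_level_reconstruction_differs_from_empirical(self, bcm):
        """History pooling means path-level reconstruction need not match the
        data: predicted N(0,1,1) is 10·(2/27) ≈ 0.74 vs 1 observed."""
        pps = estimate_progression_proportions(bcm)
        f = reconstruct_path_distribution(pps)
        predicted = 637 * f[(0, 1, 1)]
        assert float(predicted) == pytest.approx(10 * 2 / 27, abs=1e-12)
        assert predicted != bcm.count((0, 1, 1))

    def test_mean_treatments_of_reconstruction_equals_otr(self, acm):
        pps = estimate_progression_proportions(acm)
        f = reconstruct_path_distribution(pps)
        mean = sum(sum(p) * prob for p, prob in f.items())
        assert mean == otr_from_pps(pps)


def fisher_two_sided_oracle(table):
    """Enumerate all 2x2 tables with the observed margins; two-sided p is the
    hypergeometric probability mass of tables no more likely than observed."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, col1, row1)
    p = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        px = hypergeom.pmf(x, n, col1, row1)
        if px <= p_obs * (1 + 1e-9):
            p += px
    return p


class TestMarkovPropertyTest:
    def test_reference_cohort_state_v(self, bcm):
        results = markov_property_test(bcm)
        vc = [r for r in results if r.state == "V" and r.target == "C"]
        assert len(vc) == 1
        r = vc[0]
        # direct arrivals: 10 women, 1 progressed; via A: 17 women, 1 progressed
        assert set(zip(r.at_risk, r.progressed)) == {(10, 1), (17, 1)}
        assert r.method == "fisher_exact"
        assert r.p_value == pytest.approx(1.0, abs=1e-12)
        assert r.p_value == pytest.approx(
            fisher_two_sided_oracle(r.contingency), abs=1e-9
        )

    def test_gross_violation_detected(self):
        # via one history nobody progresses, via the other everybody does
        counts = {
            (0, 1, 0): 50, (0, 1, 1): 0,  # direct to V: 0/50 progress
            (1, 1, 0): 0, (1, 1, 1): 50,  # via A: 50/50 progress
            (1, 0, 0): 10,
        }
        t = PathCountTable(DEFAULT_PROTOCOL, counts)
        r = [x for x in markov_property_test(t) if x.state == "V"][0]
        assert r.p_value < 1e-10
        assert r.p_value == pytest.approx(
            fisher_two_sided_oracle(r.contingency), rel=1e-6
        )

    def test_single_history_state_skipped(self):
        t = PathCountTable(DEFAULT_PROTOCOL, {(1, 1, 0): 5, (1, 1, 1): 5})
        results = markov_property_test(t)
        skipped = [r for r in results if r.method == "skipped"]
        assert any(r.state == "V" for r in skipped)

    def test_bonferroni_scales_p(self, bcm):
        raw = markov_property_test(bcm)
        adj = markov_property_test(bcm, bonferroni=True)
        raw_p = [r.p_value for r in raw if r.method != "skipped"]
        adj_p = [r.p_value for r in adj if "Bonferroni" in (r.note or "")]
        m = len(raw_p)
        for p, q in zip(raw_p, adj_p):
            assert q == pytest.approx(min(1.0, p * m))


class TestSerialisation:
    def test_json_roundtrip(self, bcm):
        pps = estimate_progression_proportions(bcm)
        again = ProgressionProportions.from_json(pps.to_json())
        assert again.protocol.labels == pps.protocol.labels
        for k, v in pps.pp.items():
            assert float(again.pp[k]) == pytest.approx(float(v), abs=1e-15)
        obj = json.loads(pps.to_json())
        assert obj["states"] == ["O", "A", "V", "C"]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(table=path_count_tables(n_max=4))
def test_visit_identity_on_random_tables(table):
    """N·v_j = E_j holds as an exact integer identity whenever the PPs are
    estimated from the same table (history-pooled MLE)."""
    from labourpath import type_specific_ratios

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UndefinedProgressionWarning)
        pps = estimate_progression_proportions(table)
        v = visit_probabilities(pps)
    strs = type_specific_ratios(table)
    for label in table.protocol.labels:
        assert table.N * v[label] == strs.E_j[label]
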