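"""Survival and clustering metrics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines.utils import concordance_index as lifelines_cindex
from scipy.special import comb
from scipy.stats import kstest

from confact.datatypes import SurvivalTable
from confact.errors import ValidationError
from confact.metrics import (
    adjusted_rand_index,
    concordance_index,
    cox_subtype_pvalue,
    evaluate,
    normalized_mutual_information,
)
from confact.simulate import generate_survival


def _surv(time, event):
    return SurvivalTable([f"P{i}" for i in range(len(time))],
                         np.asarray(time, float), np.asarray(event, int))


def brute_ari(a, b):
    """Contingency-table ARI evaluated straight from its formula."""
    a, b = np.asarray(a), np.asarray(b)
    ua, ub = np.unique(a), np.unique(b)
    nij = np.array([[np.sum((a == x) & (b == y)) for y in ub] for x in ua])
    ai, bj, n = nij.sum(1), nij.sum(0), nij.sum()
    sum_ij = comb(nij, 2).sum()
    sum_a, sum_b = comb(ai, 2).sum(), comb(bj, 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def brute_nmi(a, b):
    """MI / arithmetic-mean-entropy from the definition."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ua, ub = np.unique(a), np.unique(b)
    mi = 0.0
    for x in ua:
        for y in ub:
            pxy = np.sum((a == x) & (b == y)) / n
            if pxy > 0:
                px, py = np.mean(a == x), np.mean(b == y)
                mi += pxy * np.log(pxy / (px * py))
    h = lambda p: -sum(q * np.log(q) for q in p if q > 0)
    ha = h([np.mean(a == x) for x in ua])
    hb = h([np.mean(b == y) for y in ub])
    denom = (ha + hb) / 2
    return 0.0 if denom == 0 else mi / denom


class TestCoxSubtypePvalue:
    def test_uniform_under_permuted_labels(self):
        surv, _ = generate_survival(
            true_risk=np.ones(300), censor_rate=0.3, seed=0
        )
        rng = np.random.default_rng(0)
        base = np.repeat([1, 2, 3], 100)
        ps = [cox_subtype_pvalue(rng.permutation(base), surv) for _ in range(50)]
        assert kstest(ps, "uniform").statistic < 0.25

    def test_strong_hazard_difference_is_detected(self):
        hits = 0
        labels = np.repeat([1, 2], 100)
        for seed in range(20):
            surv, _ = generate_survival(true_labels=labels, hazard_ratios=[8, 1],
                                        censor_rate=0.2, seed=seed)
            hits += cox_subtype_pvalue(labels, surv) < 1e-4
        assert hits >= 19

    def test_relabeling_invariance(self):
        labels = np.repeat([1, 2, 3], 40)
        surv, _ = generate_survival(true_labels=labels, hazard_ratios=[3, 2, 1],
                                    censor_rate=0.1, seed=3)
        renamed = np.choose(labels - 1, [2, 3, 1])
        assert cox_subtype_pvalue(labels, surv) == pytest.approx(
            cox_subtype_pvalue(renamed, surv), rel=1e-6
        )

    def test_degenerate_inputs_rejected(self):
        surv, _ = generate_survival(true_risk=np.ones(10), seed=0)
        with pytest.raises(ValidationError):
            cox_subtype_pvalue(np.ones(10, dtype=int), surv)
        no_events = _surv(np.arange(1, 11), np.zeros(10))
        with pytest.raises(ValidationError):
            cox_subtype_pvalue(np.repeat([1, 2], 5), no_events)


class TestConcordanceIndex:
    def test_perfect_and_inverted_orderings(self):
        surv = _surv([1, 2, 3], [1, 1, 1])
        assert concordance_index([3, 2, 1], surv) == 1.0
        assert concordance_index([1, 2, 3], surv) == 0.0

    def test_worked_censored_example(self):
        # by hand: P1 (t=1) is censored, so its pairs are not comparable;
        # comparable: (P3,P0) risk 1<2 discordant, (P3,P2) risk 1<3
        # discordant, (P2,P0) risk 3>2 concordant → 1/3
        surv = _surv([5, 1, 4, 2], [1, 0, 1, 1])
        assert concordance_index([2, 1, 3, 1], surv) == pytest.approx(1 / 3)

    def test_matches_lifelines_on_random_tie_free_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = 20
            risk = rng.normal(0, 1, n)
            time = rng.exponential(1, n) + 0.01
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                event[0] = 1
            ours = concordance_index(risk, _surv(time, event))
            ref = lifelines_cindex(time, -risk, event)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_risk_negation_complements_c_when_no_ties(self):
        rng = np.random.default_rng(1)
        risk = rng.normal(0, 1, 30)
        surv, _ = generate_survival(true_risk=np.ones(30), censor_rate=0.3, seed=1)
        assert concordance_index(risk, surv) + concordance_index(-risk, surv) == pytest.approx(1.0)

    def test_no_comparable_pairs_rejected(self):
        surv = _surv([1, 2, 3], [0, 0, 1])  # only the latest time is an event
        with pytest.raises(ValidationError):
            concordance_index([1, 2, 3], surv)


class TestPartitionAgreement:
    def test_ari_worked_cases(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0
        assert adjusted_rand_index([1, 1, 2, 2], [2, 2, 1, 1]) == 1.0
        assert adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_nmi_worked_cases(self):
        assert normalized_mutual_information([1, 1, 2, 2], [2, 2, 1, 1]) == 1.0
        assert normalized_mutual_information([1, 1, 2, 2], [1, 2, 1, 2]) == 0.0
        a, b = [1, 1, 2], [1, 2, 2]
        assert normalized_mutual_information(a, b) == pytest.approx(brute_nmi(a, b))
        assert normalized_mutual_information([1, 1, 1], [2, 2, 2]) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(1, 4), min_size=5, max_size=40),
           st.permutations([1, 2, 3, 4]))
    def test_agreement_invariant_under_label_permutation(self, a, perm):
        b = [perm[x - 1] for x in a]
        assert adjusted_rand_index(a, b) == pytest.approx(brute_ari(a, b), abs=1e-12)
        if len(set(a)) > 1:
            assert adjusted_rand_index(a, b) == pytest.approx(1.0)
            assert normalized_mutual_information(a, b) == pytest.approx(1.0)

    def test_independent_partitions_have_near_zero_ari(self):
        rng = np.random.default_rng(2)
        aris = [
            adjusted_rand_index(rng.integers(1, 4, 1000), rng.integers(1, 4, 1000))
            for _ in range(20)
        ]
        assert abs(np.mean(aris)) < 0.02

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            adjusted_rand_index([1, 2], [1, 2, 3])
        with pytest.raises(ValidationError):
            normalized_mutual_information([1], [1])


def test_evaluate_bundles_available_metrics():
    labels = np.repeat([1, 2], 50)
    surv, _ = generate_survival(true_labels=labels, hazard_ratios=[4, 1],
                                censor_rate=0.1, seed=5)
    rng = np.random.default_rng(5)
    report = evaluate(labels=labels, surv=surv,
                      risk=(labels == 1) * 2.0 + rng.normal(0, 0.1, 100), truth=labels)
    d = report.to_dict()
    assert {"cox_p", "c_index", "ari", "nmi", "n_pairs_comparable"} <= set(d)
    assert d["ari"] == 1.0
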