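"""ROC construction, Youden cutoffs, Mann-Whitney and group summaries."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ptacal.diagnostics import (
    classify_auc,
    group_summary,
    mann_whitney_u,
    optimal_cutoff,
    roc_curve,
)


# ---------------------------------------------------------------- oracles
def auc_by_pair_enumeration(pos, neg):
    """Tie-adjusted U/(n1*n2) by exhaustive enumeration of all pairs."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def best_cutoff_by_exhaustive_search(pos, neg):
    """Max Youden J over every midpoint threshold, spec tie-breaks."""
    uniq = sorted(set(pos) | set(neg))
    cands = [(a + b) / 2.0 for a, b in zip(uniq[:-1], uniq[1:])] or [uniq[0]]
    best = None
    for t in cands:
        sens = sum(v > t for v in pos) / len(pos)
        spec = sum(v <= t for v in neg) / len(neg)
        key = (sens + spec - 1.0, spec, t)
        if best is None or key > best:
            best = key
    j, spec, t = best
    return t, j


def exact_mwu_p_by_enumeration(a, b):
    """Two-sided exact Mann-Whitney p by enumerating rank assignments
    (untied data only)."""
    pooled = sorted(a + b)
    n1, n2 = len(a), len(b)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in a) - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(1, n1 + n2 + 1), n1):
        us.append(sum(combo) - n1 * (n1 + 1) / 2)
    total = len(us)
    p = 2.0 * min(sum(u <= u_obs for u in us), sum(u >= u_obs for u in us)) / total
    return u_obs, min(p, 1.0)


# ---------------------------------------------------------------- ROC
class TestRocCurve:
    def test_perfect_separation(self):
        roc = optimal_cutoff(roc_curve([4, 5, 6, 1, 2, 3], [1, 1, 1, 0, 0, 0]))
        assert roc.auc == 1.0
        assert roc.cutoff == 3.5
        assert roc.cutoff_sens == 1.0 and roc.cutoff_spec == 1.0
        assert roc.criterion == "youden"

    def test_inverted_labels_give_zero_auc(self):
        roc = roc_curve([4, 5, 6, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert roc.auc == 0.0

    def test_tied_data_matches_pair_enumeration(self):
        pos, neg = [2.0, 3.0, 5.0, 7.0], [1.0, 2.0, 4.0, 6.0]
        roc = roc_curve(pos + neg, [1] * 4 + [0] * 4)
        expected = auc_by_pair_enumeration(pos, neg)
        assert expected == pytest.approx(0.65625)  # frozen from the oracle
        assert roc.auc == pytest.approx(expected)

    def test_points_sorted_and_sensitivity_monotone(self):
        rng = np.random.default_rng(3)
        v = rng.integers(0, 10, size=40).astype(float)
        lab = rng.random(40) < 0.4
        roc = roc_curve(v, lab)
        thresholds = [p[0] for p in roc.points]
        sens = [p[1] for p in roc.points]
        assert thresholds == sorted(thresholds)
        assert all(a >= b for a, b in zip(sens, sens[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [1, 1])

    @given(
        st.lists(st.integers(0, 8), min_size=1, max_size=12),
        st.lists(st.integers(0, 8), min_size=1, max_size=12),
    )
    @settings(max_examples=150, derandomize=True)
    def test_auc_equals_tie_adjusted_u_statistic(self, pos, neg):
        roc = roc_curve([float(v) for v in pos + neg], [1] * len(pos) + [0] * len(neg))
        assert roc.auc == pytest.approx(auc_by_pair_enumeration(pos, neg))

    @given(
        st.lists(st.integers(0, 8), min_size=1, max_size=10),
        st.lists(st.integers(0, 8), min_size=1, max_size=10),
    )
    @settings(max_examples=100, derandomize=True)
    def test_label_swap_complements_auc(self, pos, neg):
        v = [float(x) for x in pos + neg]
        lab = [1] * len(pos) + [0] * len(neg)
        assert roc_curve(v, lab).auc + roc_curve(v, [1 - l for l in lab]).auc == pytest.approx(1.0)


@pytest.mark.parametrize(
    "auc,label",
    [(0.95, "excellent"), (0.873, "good"), (0.81, "good"), (0.75, "acceptable"),
     (0.7, "acceptable"), (0.677, "poor"), (0.3, "poor")],
)
def test_auc_quality_bands(auc, label):
    assert classify_auc(auc) == label


class TestOptimalCutoff:
    @given(
        st.lists(st.integers(0, 10), min_size=2, max_size=10),
        st.lists(st.integers(0, 10), min_size=2, max_size=10),
    )
    @settings(max_examples=150, derandomize=True)
    def test_agrees_with_exhaustive_midpoint_search(self, pos, neg):
        roc = optimal_cutoff(roc_curve([float(v) for v in pos + neg],
                                       [1] * len(pos) + [0] * len(neg)))
        t, j = best_cutoff_by_exhaustive_search(pos, neg)
        assert roc.cutoff_sens + roc.cutoff_spec - 1.0 == pytest.approx(j)
        if len(set(pos) | set(neg)) > 1:  # an interior midpoint exists
            assert roc.cutoff == pytest.approx(t)

    def test_degenerate_identical_values(self):
        roc = optimal_cutoff(roc_curve([5.0, 5.0, 5.0, 5.0], [1, 1, 0, 0]))
        assert roc.cutoff_sens + roc.cutoff_spec - 1.0 == pytest.approx(0.0)

    def test_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(9)
        pos = rng.lognormal(8.5, 0.7, size=20)
        neg = rng.lognormal(7.0, 0.5, size=15)
        v = np.concatenate([pos, neg])
        lab = [1] * 20 + [0] * 15
        base = optimal_cutoff(roc_curve(v, lab))
        trans = optimal_cutoff(roc_curve(np.log(v), lab))
        # J unchanged; the cutoff separates the same observations
        assert trans.cutoff_sens == base.cutoff_sens
        assert trans.cutoff_spec == base.cutoff_spec
        assert math.exp(trans.cutoff) == pytest.approx(
            math.exp(math.log(max(v[v <= base.cutoff])) / 2
                     + math.log(min(v[v > base.cutoff])) / 2)
        )


class TestMannWhitney:
    def test_tiny_exact_case(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2.0 / 6.0)

    def test_identical_multisets_give_half_u(self):
        u, _ = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(9.0 / 2.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_branch_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pooled = rng.permutation(np.arange(1.0, 13.0))  # untied
        a, b = list(pooled[:5]), list(pooled[5:11])
        u, p = mann_whitney_u(a, b)
        u_o, p_o = exact_mwu_p_by_enumeration(a, b)
        assert u == pytest.approx(u_o)
        assert p == pytest.approx(p_o)

    def test_asymptotic_branch_matches_normal_formula_with_ties(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 12, size=30).astype(float)
        b = rng.integers(2, 14, size=30).astype(float)
        u, p = mann_whitney_u(a, b)  # n1*n2 = 900 -> asymptotic
        n1, n2 = len(a), len(b)
        n = n1 + n2
        pooled = np.concatenate([a, b])
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        z = (abs(u - n1 * n2 / 2.0) - 0.5) / math.sqrt(var)  # continuity-corrected
        assert p == pytest.approx(2.0 * stats.norm.sf(z))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestGroupSummary:
    def test_constant_group(self):
        s = group_summary([5.0, 5.0, 5.0])
        assert s.mean == 5.0 and s.sem == 0.0 and s.n == 3

    def test_matches_closed_form(self):
        s = group_summary([1.0, 2.0, 3.0, 4.0])
        sd = math.sqrt(sum((v - 2.5) ** 2 for v in [1, 2, 3, 4]) / 3)
        assert s.mean == pytest.approx(2.5)
        assert s.sem == pytest.approx(sd / 2.0)

    def test_single_value_has_undefined_sem(self):
        s = group_summary([7.0])
        assert s.mean == 7.0 and s.sem is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            group_summary([])
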