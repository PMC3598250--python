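"""Ranked-list evaluation against brute-force oracles on toy universes."""

import itertools
import math

import numpy as np
import pytest

from tigress.io import CandidateEdgeSet, GoldStandard, RankedEdgeList
from tigress.evaluation import (
    confusion_at_k,
    curves_and_areas,
    ensemble_pvalues,
    overall_score,
)


def toy_setup(pairs, positives, order=None):
    """Universe + gold + a ranked list putting ``order`` first (rest appended)."""
    universe = CandidateEdgeSet(list(pairs))
    gold = GoldStandard(positive_edges=set(positives), universe=universe)
    if order is None:
        order = list(pairs)
    rows = [(r, t, float(len(order) - i)) for i, (r, t) in enumerate(order)]
    return universe, gold, RankedEdgeList(rows)


def brute_force_confusion(order, universe, positives, K):
    """Set-intersection counting, independent of any cumulative-sum logic."""
    top = set(order[:K])
    TP = len(top & positives)
    FP = len(top - positives)
    FN = len(positives - top)
    TN = len(set(universe) - top - positives)
    return TP, FP, FN, TN


def brute_force_areas(order, universe, positives):
    """Hand step integration of ROC (trapezoid) and PR (rectangles)."""
    P = len(positives)
    Nn = len(list(universe)) - P
    roc = [(0.0, 0.0)]
    pr_area = 0.0
    prev_recall = 0.0
    for K in range(1, len(order) + 1):
        TP, FP, FN, TN = brute_force_confusion(order, universe, positives, K)
        recall, fallout = TP / P, FP / Nn
        roc.append((fallout, recall))
        if recall > prev_recall:
            pr_area += (TP / K) * (recall - prev_recall)
        prev_recall = recall
    auroc = sum(
        (x2 - x1) * (y1 + y2) / 2 for (x1, y1), (x2, y2) in zip(roc, roc[1:])
    )
    return auroc, pr_area


@pytest.fixture
def six_edge_universe():
    pairs = [("T1", "G2"), ("T1", "G3"), ("T2", "G1"), ("T2", "G3"),
             ("T3", "G1"), ("T3", "G2")]
    return pairs, {("T1", "G2"), ("T2", "G3")}


class TestConfusion:
    def test_perfect_top2(self, six_edge_universe):
        pairs, pos = six_edge_universe
        order = sorted(pos) + [p for p in pairs if p not in pos]
        _, gold, ranked = toy_setup(pairs, pos, order)
        c = confusion_at_k(ranked, gold, 2)
        assert (c.TP, c.FP, c.FN, c.TN) == (2, 0, 0, 4)

    def test_worst_top2(self, six_edge_universe):
        pairs, pos = six_edge_universe
        order = [p for p in pairs if p not in pos] + sorted(pos)
        _, gold, ranked = toy_setup(pairs, pos, order)
        c = confusion_at_k(ranked, gold, 2)
        assert (c.TP, c.FP, c.FN, c.TN) == (0, 2, 2, 2)

    def test_matches_brute_force_for_all_k_and_orders(self, six_edge_universe, rng):
        pairs, pos = six_edge_universe
        for _ in range(25):
            order = [pairs[i] for i in rng.permutation(len(pairs))]
            universe, gold, ranked = toy_setup(pairs, pos, order)
            for K in range(1, len(pairs) + 1):
                c = confusion_at_k(ranked, gold, K)
                assert (c.TP, c.FP, c.FN, c.TN) == brute_force_confusion(
                    order, universe, pos, K
                )

    def test_k_beyond_list_clamped(self, six_edge_universe):
        pairs, pos = six_edge_universe
        _, gold, ranked = toy_setup(pairs, pos)
        c = confusion_at_k(ranked, gold, 100)
        assert c.K == len(pairs) and c.FN == 0 and c.TN == 0

    def test_truncated_list_still_covers_universe(self, six_edge_universe):
        # missing universe pairs are appended with score -inf, so counts at
        # full K are identical to a complete list
        pairs, pos = six_edge_universe
        _, gold, ranked = toy_setup(pairs, pos)
        truncated = ranked.head(2)
        c = confusion_at_k(truncated, gold, len(pairs))
        assert c.TP == len(pos) and c.TN == 0


class TestCurves:
    def test_perfect_and_reversed_rankings(self, six_edge_universe):
        pairs, pos = six_edge_universe
        perfect = sorted(pos) + sorted(set(pairs) - pos)
        _, gold, ranked = toy_setup(pairs, pos, perfect)
        s = curves_and_areas(ranked, gold)
        assert s.auroc == pytest.approx(1.0) and s.aupr == pytest.approx(1.0)
        _, gold, reversed_ = toy_setup(pairs, pos, perfect[::-1])
        assert curves_and_areas(reversed_, gold).auroc == pytest.approx(0.0)

    def test_areas_match_hand_integration_exhaustively(self):
        # all 120 orderings of a 5-edge universe with 2 positives
        pairs = [("A", "b"), ("A", "c"), ("B", "a"), ("B", "c"), ("C", "a")]
        pos = {("A", "c"), ("C", "a")}
        for order in itertools.permutations(pairs):
            universe, gold, ranked = toy_setup(pairs, pos, list(order))
            s = curves_and_areas(ranked, gold)
            auroc, aupr = brute_force_areas(list(order), universe, pos)
            assert s.auroc == pytest.approx(auroc, abs=1e-12)
            assert s.aupr == pytest.approx(aupr, abs=1e-12)

    def test_matches_sklearn_auroc(self, rng):
        from sklearn.metrics import average_precision_score, roc_auc_score

        pairs = [(f"T{i}", f"G{j}") for i in range(5) for j in range(5) if i != j]
        pos = {pairs[i] for i in rng.choice(len(pairs), size=6, replace=False)}
        for _ in range(10):
            order = [pairs[i] for i in rng.permutation(len(pairs))]
            _, gold, ranked = toy_setup(pairs, pos, order)
            s = curves_and_areas(ranked, gold)
            y_true = [p in pos for p in order]
            y_score = [len(order) - i for i in range(len(order))]
            assert s.auroc == pytest.approx(roc_auc_score(y_true, y_score), abs=1e-12)
            assert s.aupr == pytest.approx(
                average_precision_score(y_true, y_score), abs=1e-12
            )

    def test_random_ranking_auroc_centers_on_half(self, rng):
        pairs = [(f"T{i}", f"G{j}") for i in range(6) for j in range(6) if i != j]
        pos = set(pairs[:10])
        aurocs = []
        for _ in range(1000):
            order = [pairs[i] for i in rng.permutation(len(pairs))]
            _, gold, ranked = toy_setup(pairs, pos, order)
            aurocs.append(curves_and_areas(ranked, gold).auroc)
        aurocs = np.array(aurocs)
        se = aurocs.std(ddof=1) / math.sqrt(len(aurocs))
        assert abs(aurocs.mean() - 0.5) < 3 * se

    def test_reversal_complement_identity(self, rng):
        pairs = [(f"T{i}", f"G{j}") for i in range(4) for j in range(4) if i != j]
        pos = set(pairs[:4])
        for _ in range(20):
            order = [pairs[i] for i in rng.permutation(len(pairs))]
            _, gold, fwd = toy_setup(pairs, pos, order)
            _, _, rev = toy_setup(pairs, pos, order[::-1])
            a = curves_and_areas(fwd, gold).auroc
            b = curves_and_areas(rev, gold).auroc
            assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_universe_rejected(self):
        pairs = [("A", "b"), ("A", "c")]
        _, gold, ranked = toy_setup(pairs, set(pairs))
        with pytest.raises(ValueError, match="positive and one negative"):
            curves_and_areas(ranked, gold)


class TestEnsemblePvalues:
    @pytest.fixture
    def universe(self, rng):
        pairs = [(f"T{i}", f"G{j}") for i in range(5) for j in range(5) if i != j]
        pos = {pairs[i] for i in rng.choice(len(pairs), size=5, replace=False)}
        return pairs, pos

    def test_identical_ensemble_gives_p_one(self, universe):
        # every randomized list reproduces the target exactly, so the chance
        # of an equal-or-better area is 1 by construction
        pairs, pos = universe
        _, gold, ranked = toy_setup(pairs, pos)
        s = ensemble_pvalues(ranked, [ranked] * 5, gold, n_random=100, rng=0)
        assert s.p_auroc_raw == pytest.approx(1.0) and s.p_aupr_raw == pytest.approx(1.0)

    def test_dominant_list_hits_empirical_floor(self, universe, rng):
        pairs, pos = universe
        perfect = sorted(pos) + sorted(set(pairs) - pos)
        _, gold, target = toy_setup(pairs, pos, perfect)
        ensemble = []
        for _ in range(6):
            order = [pairs[i] for i in rng.permutation(len(pairs))]
            ensemble.append(toy_setup(pairs, pos, order)[2])
        s = ensemble_pvalues(target, ensemble, gold, n_random=1000, rng=1)
        assert s.p_aupr_raw <= 1 / 1001 + 1e-12
        assert s.p_auroc <= s.p_auroc_raw  # extrapolated tail never exceeds raw

    def test_ensemble_order_invariance(self, universe, rng):
        pairs, pos = universe
        _, gold, target = toy_setup(pairs, pos)
        ensemble = [
            toy_setup(pairs, pos, [pairs[i] for i in rng.permutation(len(pairs))])[2]
            for _ in range(4)
        ]
        a = ensemble_pvalues(target, ensemble, gold, n_random=200, rng=7)
        b = ensemble_pvalues(target, ensemble[::-1], gold, n_random=200, rng=7)
        # same seeded null scale: p-values agree to within Monte-Carlo noise
        assert abs(math.log10(a.p_aupr_raw) - math.log10(b.p_aupr_raw)) < 0.5

    def test_single_member_ensemble_warns(self, universe):
        pairs, pos = universe
        _, gold, target = toy_setup(pairs, pos)
        with pytest.warns(UserWarning, match="degenerate"):
            ensemble_pvalues(target, [target], gold, n_random=100, rng=0)


class TestOverallScore:
    @pytest.mark.parametrize(
        "p_aupr, p_auroc, expected",
        [(1e-100, 1e-100, 100.0), (1.0, 1.0, 0.0), (1e-4, 1e-2, 3.0)],
    )
    def test_log_arithmetic(self, p_aupr, p_auroc, expected):
        assert overall_score(p_aupr, p_auroc) == pytest.approx(expected)

    def test_symmetric_and_decreasing(self):
        assert overall_score(1e-3, 1e-7) == overall_score(1e-7, 1e-3)
        assert overall_score(1e-4, 1e-2) > overall_score(1e-3, 1e-2)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            overall_score(bad, 0.5)
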