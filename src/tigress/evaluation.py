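"""DREAM-style evaluation of a ranked edge list against a gold standard.

Confusion counts at each cutoff K, the ROC curve (recall vs fall-out), the
precision-recall curve, their areas (AUROC by trapezoid, AUPR by step-wise
rectangle sum), ensemble-randomization p-values, and the combined overall
score -(1/2) log10(P_AUPR * P_AUROC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import GoldStandard, RankedEdgeList

__all__ = [
    "ConfusionCounts",
    "EvaluationSummary",
    "confusion_at_k",
    "curves_and_areas",
    "ensemble_pvalues",
    "overall_score",
]


@dataclass
class ConfusionCounts:
    K: int
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else math.nan

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else math.nan

    @property
    def fallout(self) -> float:
        return self.FP / (self.FP + self.TN) if self.FP + self.TN else math.nan


@dataclass
class EvaluationSummary:
    roc_points: np.ndarray  # (K+1, 2): (fall-out, recall), starting at (0, 0)
    pr_points: np.ndarray   # (K, 2): (recall, precision)
    auroc: float
    aupr: float
    p_auroc: float | None = None
    p_aupr: float | None = None
    p_auroc_raw: float | None = None
    p_aupr_raw: float | None = None
    overall: float | None = None


def _labels_in_rank_order(ranked: RankedEdgeList, gold: GoldStandard) -> np.ndarray:
    """0/1 gold labels of the evaluation universe in prediction-rank order.

    Universe pairs absent from the (possibly truncated) prediction list are
    appended after it in the deterministic tie-break order with an implicit
    score of -infinity, so every metric is defined over the full universe.
    """
    universe = gold.evaluation_universe()
    in_universe = set(universe)
    listed = [pair for pair in ranked.pairs() if pair in in_universe]
    listed_set = set(listed)
    missing = sorted(pair for pair in universe if pair not in listed_set)
    order = listed + missing
    pos = gold.positive_edges
    return np.fromiter((pair in pos for pair in order), dtype=bool, count=len(order))


def confusion_at_k(ranked: RankedEdgeList, gold: GoldStandard, K: int) -> ConfusionCounts:
    """TP/FP/FN/TN when the top K predictions are called positive."""
    if K < 1:
        raise ValueError("K must be >= 1")
    labels = _labels_in_rank_order(ranked, gold)
    N = labels.size
    K_eff = min(K, N)
    P = int(labels.sum())
    TP = int(labels[:K_eff].sum())
    FP = K_eff - TP
    FN = P - TP
    TN = N - K_eff - FN
    return ConfusionCounts(K=K_eff, TP=TP, FP=FP, FN=FN, TN=TN)


def curves_and_areas(ranked: RankedEdgeList, gold: GoldStandard) -> EvaluationSummary:
    """Sweep K over the whole universe and integrate the ROC and PR curves.

    AUROC: trapezoidal integration of recall against fall-out (equals the
    Mann-Whitney statistic for tie-free rankings).  AUPR: step-wise
    rectangle sum — precision at each new true positive times the recall
    increment, with no linear interpolation between PR points.
    """
    labels = _labels_in_rank_order(ranked, gold)
    P = int(labels.sum())
    N_neg = labels.size - P
    if P == 0 or N_neg == 0:
        raise ValueError("evaluation universe needs at least one positive and one negative")
    tp = np.cumsum(labels)
    fp = np.cumsum(~labels)
    recall = tp / P
    fallout = fp / N_neg
    k = np.arange(1, labels.size + 1)
    precision = tp / k

    roc = np.column_stack([np.concatenate([[0.0], fallout]),
                           np.concatenate([[0.0], recall])])
    auroc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
    # rectangle sum: each true positive contributes precision(k) * (1/P)
    aupr = float(precision[labels].sum() / P)
    pr = np.column_stack([recall, precision])
    return EvaluationSummary(roc_points=roc, pr_points=pr, auroc=auroc, aupr=aupr)


def _randomized_list(
    ensemble_pairs: list[list[tuple[str, str]]],
    length: int,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """One position-wise random list drawn across the ensemble.

    For each rank position an edge at the same position is drawn from a
    random ensemble member.  Duplicates keep their first occurrence; the
    list is then topped up with further random draws from the ensemble's
    remaining edges so that prediction lists never repeat a pair.
    """
    n_members = len(ensemble_pairs)
    out: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for pos in range(length):
        members = [m for m in ensemble_pairs if len(m) > pos]
        if not members:
            break
        pick = members[rng.integers(len(members))][pos]
        if pick not in seen:
            seen.add(pick)
            out.append(pick)
    if len(out) < length:
        pool = list({e for m in ensemble_pairs for e in m} - seen)
        pool.sort()
        rng.shuffle(pool)
        out.extend(pool[: length - len(out)])
    return out


def _tail_pvalue(null_values: np.ndarray, observed: float) -> tuple[float, float]:
    """(raw, extrapolated) upper-tail p-values of ``observed`` under a null sample.

    Raw: add-one empirical estimate (#{null >= obs} + 1) / (n + 1).
    Extrapolated: exponential fit to the exceedances above the upper decile
    — P(X >= x) ~ 0.1 exp(-(x - q90) / lam) — used when the observation
    falls beyond the sampled tail, where the empirical estimate saturates.
    """
    n = null_values.size
    raw = (float((null_values >= observed).sum()) + 1.0) / (n + 1.0)
    q90 = float(np.quantile(null_values, 0.9))
    exceed = null_values[null_values > q90] - q90
    if observed <= q90 or exceed.size < 5 or exceed.mean() <= 0:
        return raw, raw
    lam = float(exceed.mean())
    extrapolated = 0.1 * math.exp(-(observed - q90) / lam)
    return raw, min(raw, max(extrapolated, 1e-300))


def ensemble_pvalues(
    target_list: RankedEdgeList,
    ensemble: list[RankedEdgeList],
    gold: GoldStandard,
    n_random: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> EvaluationSummary:
    """P-values for AUPR and AUROC against a position-wise randomized null.

    The null distribution is built from ``n_random`` synthetic prediction
    lists, each assembled by drawing, for every rank position, an edge at
    the same position from a random member of the ensemble of prediction
    lists.  The returned p-values estimate the probability of an equal or
    larger AUPR (resp. AUROC) by chance; both the raw add-one empirical
    value and the tail-extrapolated value are reported, and the combined
    overall score uses the extrapolated ones.
    """
    if not ensemble:
        raise ValueError("ensemble of prediction lists must be non-empty")
    if n_random < 100:
        raise ValueError("need at least 100 randomizations for a usable null")
    if len(ensemble) == 1:
        import warnings

        warnings.warn("ensemble of size 1: the randomized null is degenerate", stacklevel=2)
    rng = np.random.default_rng(rng)
    base = curves_and_areas(target_list, gold)
    ensemble_pairs = [lst.pairs() for lst in ensemble]
    length = len(target_list)
    null_auroc = np.empty(n_random)
    null_aupr = np.empty(n_random)
    for i in range(n_random):
        pairs = _randomized_list(ensemble_pairs, length, rng)
        synthetic = RankedEdgeList(
            [(r, t, float(length - j)) for j, (r, t) in enumerate(pairs)]
        )
        summ = curves_and_areas(synthetic, gold)
        null_auroc[i] = summ.auroc
        null_aupr[i] = summ.aupr
    p_auroc_raw, p_auroc = _tail_pvalue(null_auroc, base.auroc)
    p_aupr_raw, p_aupr = _tail_pvalue(null_aupr, base.aupr)
    return EvaluationSummary(
        roc_points=base.roc_points,
        pr_points=base.pr_points,
        auroc=base.auroc,
        aupr=base.aupr,
        p_auroc=p_auroc,
        p_aupr=p_aupr,
        p_auroc_raw=p_auroc_raw,
        p_aupr_raw=p_aupr_raw,
        overall=overall_score(p_aupr, p_auroc),
    )


def overall_score(p_aupr: float, p_auroc: float) -> float:
    """Combined score: the mean of the two -log10 p-values.

    overall = -(1/2) log10(P_AUPR * P_AUROC); 0 when both p-values are 1,
    and symmetric and strictly decreasing in each argument.
    """
    if not (0.0 < p_aupr <= 1.0) or not (0.0 < p_auroc <= 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    return -0.5 * math.log10(p_aupr * p_auroc)
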