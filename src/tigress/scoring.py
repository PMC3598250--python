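"""Turn selection frequencies into per-edge scores and a global ranking.

Two closed-form scores, both expressible as expectations E[phi(H_t)] of a
non-increasing function of the entry rank H_t:

* original score  s(t, g) = F(g, t, L) — the classical stability-selection
  score, the frequency of selection within the top L steps
  (phi(h) = 1 for h <= L);
* area score      s(t, g) = (1/L) sum_{l<=L} F(g, t, l) — the area under
  the stability curve, rewarding TFs that enter not only within the top L
  but with small rank (phi(h) = L + 1 - h, up to the 1/L factor).

Both are naturally normalized per target gene — sum_t s_original = L and
sum_t s_area = (L+1)/2 whenever no run stopped early — so scores are
aggregated across targets without further normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CandidateEdgeSet, RankedEdgeList
from .stability import FrequencyTensor

__all__ = [
    "ScoreFunction",
    "ScoreMatrix",
    "phi_original",
    "phi_area",
    "score_original",
    "score_area",
    "score_phi",
    "aggregate_edges",
    "threshold_edges",
]


@dataclass
class ScoreFunction:
    """A rank-score function phi: {1..L} -> R+, non-increasing, zero beyond L."""

    name: str
    values: np.ndarray  # values[h-1] = phi(h), h = 1..L

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("phi must map the ranks 1..L")
        if (self.values < 0).any():
            raise ValueError("phi must be non-negative")
        if (np.diff(self.values) > 1e-12).any():
            raise ValueError("phi must be non-increasing in the rank")

    @property
    def L(self) -> int:
        return self.values.size


def phi_original(L: int) -> ScoreFunction:
    """Indicator of selection within the top L: phi(h) = 1 for h <= L."""
    return ScoreFunction("original", np.ones(L))


def phi_area(L: int) -> ScoreFunction:
    """Linearly decaying rank reward: phi(h) = L + 1 - h for h <= L."""
    return ScoreFunction("area", np.arange(L, 0, -1, dtype=float))


@dataclass
class ScoreMatrix:
    """Per-edge scores s(t, g); axes (target gene, candidate TF)."""

    s: np.ndarray
    gene_ids: list[str]
    tf_ids: list[str]
    method: str
    L_used: int

    def score_of(self, tf_id: str, gene_id: str) -> float:
        return float(self.s[self.gene_ids.index(gene_id), self.tf_ids.index(tf_id)])


def score_original(F: FrequencyTensor) -> ScoreMatrix:
    """s(t, g) = F(g, t, L): selection frequency within the top L steps."""
    return ScoreMatrix(
        s=F.F[:, :, F.L - 1].copy(),
        gene_ids=F.gene_ids,
        tf_ids=F.tf_ids,
        method="original",
        L_used=F.L,
    )


def score_area(F: FrequencyTensor) -> ScoreMatrix:
    """s(t, g) = (1/L) sum_{l=1..L} F(g, t, l): area under the stability curve."""
    return ScoreMatrix(
        s=F.F.mean(axis=2),
        gene_ids=F.gene_ids,
        tf_ids=F.tf_ids,
        method="area",
        L_used=F.L,
    )


def score_phi(F: FrequencyTensor, phi: ScoreFunction) -> ScoreMatrix:
    """Generic rank-expectation score s(t, g) = E[phi(H_t)].

    The per-run rank distribution is recovered from the frequency tensor by
    differencing: P(H = h) = F(., ., h) - F(., ., h-1) with F(., ., 0) = 0,
    since F is by definition the empirical CDF P(H <= l).  With the
    canonical phi functions this reproduces the closed forms exactly:
    phi_original gives score_original, phi_area gives L * score_area (the
    area score carries an extra 1/L normalization that the raw expectation
    does not).  Generic-phi scores are reported unnormalized.
    """
    if phi.L != F.L:
        raise ValueError(f"phi is defined on ranks 1..{phi.L} but the tensor has L={F.L}")
    pmf = np.diff(F.F, axis=2, prepend=0.0)
    s = pmf @ phi.values
    return ScoreMatrix(
        s=s, gene_ids=F.gene_ids, tf_ids=F.tf_ids, method=f"phi:{phi.name}", L_used=F.L
    )


def aggregate_edges(S: ScoreMatrix, E: CandidateEdgeSet) -> RankedEdgeList:
    """Rank all candidate regulations globally by decreasing score.

    Scores are already normalized per target gene, so no cross-gene
    renormalization is applied.  Ties break lexicographically on
    (regulator, target) for reproducibility.
    """
    g_index = {g: i for i, g in enumerate(S.gene_ids)}
    t_index = {t: j for j, t in enumerate(S.tf_ids)}
    rows = []
    for t, g in E:
        try:
            rows.append((t, g, float(S.s[g_index[g], t_index[t]])))
        except KeyError as exc:
            raise ValueError(f"candidate edge ({t}, {g}) not covered by the score matrix") from exc
    return RankedEdgeList.from_unsorted(rows)


def threshold_edges(ranked: RankedEdgeList, delta: float) -> RankedEdgeList:
    """Keep predictions with score strictly above delta.

    Larger delta keeps fewer predictions; for delta' > delta the result is
    a subset (nested thresholding).
    """
    return RankedEdgeList([row for row in ranked.rows if row[2] > delta])
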