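"""Stability selection: the randomized resampling loop around LARS.

For each target gene g the expression of g is regressed on its candidate
TFs.  R/2 times, the experiments are split into two halves; each half is an
independent run in which the candidate-TF columns are multiplied by random
weights drawn uniformly from [alpha, 1] and LARS is run for L steps.  Over
the R runs this yields, for every candidate TF t and step l, the selection
frequency F(g, t, l) = fraction of runs in which t entered within the first
l steps — the empirical CDF of t's entry rank H_t.

Determinism: every (target, split) pair gets its own RNG substream derived
from the master seed, so results are bit-identical regardless of execution
order or worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .io import ExpressionMatrix, RegulatorSet
from .lars import lars_select

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityConfig",
    "FrequencyTensor",
    "split_experiments",
    "reweight_tfs",
    "run_stability",
]

PER_TF_PER_RUN = "per-tf-per-run"
PER_TF_PER_SAMPLE = "per-tf-per-sample"


@dataclass
class StabilityConfig:
    """Parameters of the stability-selection loop.

    R
        total number of LARS runs; must be even (each random split of the
        experiments contributes two runs, one per half).  Larger R estimates
        the selection frequencies better; the recommended operating point in
        the source method is R = 10,000, with R = 1,000 already adequate on
        small networks.
    L
        LARS steps per run.  L = 2 works well when the TF set is small;
        larger TF sets favor larger L.
    alpha
        lower bound of the uniform reweighting interval [alpha, 1].
        alpha = 1 disables weight randomization; alpha = 0 is maximal
        randomization; 0.4 is the recommended default.
    reweight_granularity
        "per-tf-per-run" (one weight per TF column per run, the classical
        randomized-lasso perturbation; default) or "per-tf-per-sample"
        (an independent weight for every (TF, experiment) entry).
    resample
        when False the half-sample splitting is disabled and every run sees
        all experiments (diagnostic mode: with alpha = 1 as well, all runs
        are identical and frequencies are 0/1).
    """

    R: int = 1000
    L: int = 2
    alpha: float = 0.4
    score_method: str = "area"
    reweight_granularity: str = PER_TF_PER_RUN
    master_seed: int = 0
    resample: bool = True
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.R <= 0 or self.R % 2:
            raise ValueError(
                f"R must be a positive even number of runs (R/2 splits, two runs each); got {self.R}"
            )
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1]; got {self.alpha}")
        if self.L < 1:
            raise ValueError(f"L must be >= 1; got {self.L}")
        if self.reweight_granularity not in (PER_TF_PER_RUN, PER_TF_PER_SAMPLE):
            raise ValueError(f"unknown reweighting granularity {self.reweight_granularity!r}")
        if self.score_method not in ("area", "original"):
            raise ValueError(f"unknown score method {self.score_method!r}")


@dataclass
class FrequencyTensor:
    """Selection frequencies F(g, t, l) with their underlying counts.

    Axes: target gene (in ``gene_ids`` order), candidate TF (in ``tf_ids``
    order), LARS step l = 1..L.  Entries where t is the target itself are
    zero and excluded from every candidate set.  ``shortfall[g, l-1]`` is
    the total number of selections missing at step l because runs stopped
    early (path shorter than l); when it is zero the conservation identity
    sum_t F(g, t, l) = l holds exactly.
    """

    F: np.ndarray
    counts: np.ndarray
    gene_ids: list[str]
    tf_ids: list[str]
    L: int
    R: int
    R_effective: np.ndarray
    shortfall: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.shortfall is None:
            self.shortfall = np.zeros((len(self.gene_ids), self.L), dtype=int)

    @property
    def n_targets(self) -> int:
        return len(self.gene_ids)

    def candidate_mask(self) -> np.ndarray:
        """Boolean (targets x TFs): True where the TF is a candidate (t != g)."""
        tf_pos = np.array([self.gene_ids.index(t) for t in self.tf_ids])
        g_idx = np.arange(len(self.gene_ids))
        return tf_pos[None, :] != g_idx[:, None]


def split_experiments(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint split of {0..n-1} into halves of (near-)equal size."""
    if n < 4:
        raise ValueError(f"need at least 4 experiments to split into usable halves; got {n}")
    perm = rng.permutation(n)
    return perm[: n // 2], perm[n // 2:]


def reweight_tfs(
    design: np.ndarray,
    alpha: float,
    granularity: str = PER_TF_PER_RUN,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Multiply candidate-TF expression by random weights from U[alpha, 1].

    With alpha = 1 the draw is degenerate and the output equals the input
    exactly.  Column granularity perturbs each TF as a whole (one weight per
    TF per run); sample granularity draws an independent weight for every
    (TF, experiment) entry.
    """
    if rng is None:
        rng = np.random.default_rng()
    m, q = design.shape
    if granularity == PER_TF_PER_RUN:
        w = rng.uniform(alpha, 1.0, size=q)
        return design * w
    if granularity == PER_TF_PER_SAMPLE:
        return design * rng.uniform(alpha, 1.0, size=(m, q))
    raise ValueError(f"unknown reweighting granularity {granularity!r}")


def _seed_key(master_seed: int, *parts: int) -> np.random.SeedSequence:
    # SeedSequence entropy must be non-negative
    return np.random.SeedSequence([master_seed & 0x7FFFFFFF, *parts])


def _target_counts(
    X: np.ndarray,
    g: int,
    cand_cols: np.ndarray,
    tf_col_of: np.ndarray,
    q: int,
    cfg: StabilityConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Selection-rank counts for one target gene over all R runs.

    Returns (counts_at_rank: q x L, shortfall: L).
    """
    n = X.shape[0]
    L_eff = min(cfg.L, cand_cols.size)
    counts_at_rank = np.zeros((q, cfg.L), dtype=np.int64)
    path_len_hist = np.zeros(cfg.L + 1, dtype=np.int64)

    D_full = X[:, cand_cols]
    y_full = X[:, g]
    n_splits = cfg.R // 2

    for s_i in range(n_splits):
        rng = np.random.default_rng(_seed_key(cfg.master_seed, g, s_i))
        if cfg.resample:
            halves = split_experiments(n, rng)
        else:
            idx = np.arange(n)
            halves = (idx, idx)
        for half in halves:
            D = reweight_tfs(D_full[half], cfg.alpha, cfg.reweight_granularity, rng)
            # columns keep their random weights (no re-standardization, which
            # would undo them); design and response are re-centered on the half
            D = D - D.mean(axis=0)
            y = y_full[half]
            y = y - y.mean()
            path = lars_select(D, y, L_eff, _validate=False)
            for h, t in enumerate(path.entry_order):
                counts_at_rank[tf_col_of[cand_cols[t]], h] += 1
            path_len_hist[path.n_steps_run] += 1

    # selections missing at step l because some paths stopped before l
    lens = np.arange(cfg.L + 1)
    shortfall = np.array(
        [int(np.sum(np.maximum(l - lens, 0) * path_len_hist)) for l in range(1, cfg.L + 1)]
    )
    return counts_at_rank, shortfall


def run_stability(
    X: ExpressionMatrix, regs: RegulatorSet, cfg: StabilityConfig
) -> FrequencyTensor:
    """Run the full resampling loop for every target gene.

    Each target is an independent regression problem; targets are
    embarrassingly parallel and accumulation is deterministic for any
    ``n_jobs`` because every (target, split) has its own seeded substream.
    """
    if not X.standardized:
        raise ValueError("expression matrix must be standardized before stability selection")
    gene_ids = X.gene_ids
    p = len(gene_ids)
    tf_cols = np.array([gene_ids.index(t) for t in regs.tf_ids], dtype=int)
    q = tf_cols.size
    tf_col_of = np.full(p, -1, dtype=int)
    tf_col_of[tf_cols] = np.arange(q)

    def one_target(g: int):
        cand = tf_cols[tf_cols != g]
        if cand.size == 0:
            # no candidate regulators: every selection is missing at every step
            return (
                np.zeros((q, cfg.L), dtype=np.int64),
                np.arange(1, cfg.L + 1, dtype=np.int64) * cfg.R,
            )
        try:
            return _target_counts(X.values, g, cand, tf_col_of, q, cfg)
        except Exception as exc:
            raise RuntimeError(f"stability selection failed for target {gene_ids[g]}") from exc

    if cfg.n_jobs == 1:
        results = [one_target(g) for g in range(p)]
    else:
        results = Parallel(n_jobs=cfg.n_jobs)(delayed(one_target)(g) for g in range(p))

    counts_at_rank = np.stack([r[0] for r in results])           # (p, q, L)
    shortfall = np.stack([r[1] for r in results])                # (p, L)
    counts = np.cumsum(counts_at_rank, axis=2)                   # selections within l steps
    F = counts / float(cfg.R)

    n_short = int((shortfall[:, -1] > 0).sum())
    if n_short:
        logger.debug("%d targets had early-stopped LARS runs (frequency shortfall)", n_short)

    return FrequencyTensor(
        F=F,
        counts=counts,
        gene_ids=list(gene_ids),
        tf_ids=list(regs.tf_ids),
        L=cfg.L,
        R=cfg.R,
        R_effective=np.full(p, cfg.R, dtype=int),
        shortfall=shortfall,
    )
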