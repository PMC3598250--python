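"""Synthetic linear gene regulatory networks and matching expression data.

The generator produces the ground truth the inference method assumes: a
directed acyclic network from a designated TF subset to target genes, with
each gene's expression a sparse linear combination of its regulators plus
Gaussian noise.  Every file the pipeline consumes (expression matrix, TF
list, gold standard) can be emulated with a known truth, so the whole tool
chain is testable without external benchmark downloads.

This is deliberately a linear-Gaussian generator, not a kinetic ODE
simulator: it matches the model class the inference method fits, giving
clean parameter-recovery semantics.  Real compendia add nonlinearity,
feedback loops, hidden confounders and heteroscedastic noise that this
generator does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import (
    CandidateEdgeSet,
    ExpressionMatrix,
    GoldStandard,
    RegulatorSet,
    build_candidates,
    standardize,
)

__all__ = ["SyntheticNetwork", "generate_network", "simulate_expression", "write_benchmark_files"]


@dataclass
class SyntheticNetwork:
    """A known linear ground-truth network."""

    gene_ids: list[str]
    tf_ids: list[str]
    regs: RegulatorSet
    candidates: CandidateEdgeSet
    gold: GoldStandard
    coefficients: dict[tuple[str, str], float]  # beta on each true edge, non-zero
    noise_sd: float

    @property
    def n_edges(self) -> int:
        return len(self.coefficients)


def generate_network(
    p: int = 50,
    q: int = 10,
    mean_out_degree: float = 3.0,
    beta_range: tuple[float, float] = (0.5, 1.5),
    noise_sd: float = 0.5,
    seed: int | np.random.SeedSequence | None = 0,
) -> SyntheticNetwork:
    """Sample a random directed acyclic TF->target network.

    The first ``q`` genes are the transcription factors.  Acyclicity comes
    from an ordering constraint: a TF may regulate any gene with a strictly
    larger index, so all regulation flows "downstream".  About
    ``q * mean_out_degree`` edges are drawn uniformly without replacement
    from the allowed pairs; each edge coefficient has magnitude uniform in
    ``beta_range`` and a random sign, keeping every true effect bounded
    away from zero.
    """
    if q > p:
        raise ValueError(f"cannot have more TFs ({q}) than genes ({p})")
    if mean_out_degree < 0:
        raise ValueError("mean out-degree must be non-negative")
    if not 0 < beta_range[0] <= beta_range[1]:
        raise ValueError("beta magnitudes must satisfy 0 < lo <= hi")
    if noise_sd <= 0:
        raise ValueError("noise standard deviation must be positive")
    rng = np.random.default_rng(seed)
    width = len(str(p))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(p)]
    tf_ids = gene_ids[:q]

    allowed = [(t, g) for t in range(q) for g in range(t + 1, p)]
    n_edges = min(int(round(q * mean_out_degree)), len(allowed))
    if n_edges == 0 and mean_out_degree > 0 and allowed:
        raise ValueError("requested edge count rounds to zero; increase mean_out_degree")
    chosen = rng.choice(len(allowed), size=n_edges, replace=False) if n_edges else []
    coefficients: dict[tuple[str, str], float] = {}
    for idx in chosen:
        t, g = allowed[idx]
        beta = rng.uniform(*beta_range) * rng.choice([-1.0, 1.0])
        coefficients[(gene_ids[t], gene_ids[g])] = float(beta)

    regs, candidates = build_candidates(gene_ids, tf_ids)
    gold = None
    if coefficients:
        gold = GoldStandard(
            positive_edges=set(coefficients), universe=candidates, n_excluded=0
        )
    return SyntheticNetwork(
        gene_ids=gene_ids,
        tf_ids=tf_ids,
        regs=regs,
        candidates=candidates,
        gold=gold,
        coefficients=coefficients,
        noise_sd=noise_sd,
    )


def simulate_expression(
    net: SyntheticNetwork,
    n: int = 100,
    seed: int | np.random.SeedSequence | None = 0,
    standardized: bool = True,
) -> ExpressionMatrix:
    """Simulate n experiments from the linear model X_g = sum_t beta * X_t + eps.

    Genes without regulators are sources drawn from a standard normal;
    regulated genes are evaluated in topological (index) order as the
    beta-weighted sum of their regulators plus Normal(0, noise_sd^2) noise.
    The matrix is standardized per gene by default, as the inference
    pipeline expects.
    """
    if n < 4:
        raise ValueError("need at least 4 experiments")
    rng = np.random.default_rng(seed)
    p = len(net.gene_ids)
    index = {g: i for i, g in enumerate(net.gene_ids)}
    parents: list[list[tuple[int, float]]] = [[] for _ in range(p)]
    for (t, g), beta in net.coefficients.items():
        parents[index[g]].append((index[t], beta))

    X = np.empty((n, p))
    for j in range(p):  # index order is a topological order by construction
        if not parents[j]:
            X[:, j] = rng.standard_normal(n)
        else:
            mean = np.zeros(n)
            for i, beta in parents[j]:
                mean += beta * X[:, i]
            X[:, j] = mean + net.noise_sd * rng.standard_normal(n)

    M = ExpressionMatrix(X, net.gene_ids, standardized=False)
    return standardize(M) if standardized else M


def write_benchmark_files(
    net: SyntheticNetwork, X: ExpressionMatrix, outdir
) -> dict[str, Path]:
    """Write the three standard pipeline inputs into ``outdir``.

    expression.tsv (header of gene ids + one row per experiment),
    tf_list.txt (one TF id per line) and gold_standard.tsv
    (regulator, target, 1).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "tf_list": outdir / "tf_list.txt",
        "gold_standard": outdir / "gold_standard.tsv",
    }
    with open(paths["expression"], "w") as fh:
        fh.write("\t".join(X.gene_ids) + "\n")
        for row in X.values:
            fh.write("\t".join(f"{v:.8g}" for v in row) + "\n")
    with open(paths["tf_list"], "w") as fh:
        fh.writelines(t + "\n" for t in net.tf_ids)
    with open(paths["gold_standard"], "w") as fh:
        for t, g in sorted(net.coefficients):
            fh.write(f"{t}\t{g}\t1\n")
    return paths
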