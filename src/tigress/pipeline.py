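"""High-level inference entry point: expression in, ranked edge list out."""

from __future__ import annotations

from .io import (
    CandidateEdgeSet,
    ExpressionMatrix,
    RankedEdgeList,
    RegulatorSet,
    build_candidates,
    standardize,
)
from .scoring import aggregate_edges, score_area, score_original
from .stability import FrequencyTensor, StabilityConfig, run_stability

__all__ = ["infer_network"]


def infer_network(
    X: ExpressionMatrix,
    tf_ids: list[str] | None = None,
    cfg: StabilityConfig | None = None,
    return_frequencies: bool = False,
) -> RankedEdgeList | tuple[RankedEdgeList, FrequencyTensor]:
    """Run the full inference pipeline on an expression matrix.

    Standardizes the data if needed, builds the candidate universe (all
    genes are candidate regulators when ``tf_ids`` is None — directionality
    mode), runs stability selection and returns the globally ranked edge
    list under the configured scoring method.
    """
    cfg = cfg or StabilityConfig()
    if not X.standardized:
        X = standardize(X)
    regs, candidates = build_candidates(X.gene_ids, tf_ids)
    F = run_stability(X, regs, cfg)
    scorer = score_area if cfg.score_method == "area" else score_original
    ranked = aggregate_edges(scorer(F), candidates)
    if return_frequencies:
        return ranked, F
    return ranked
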