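"""Reading, writing and standardizing expression data and edge lists.

File dialects follow the DREAM network-inference challenges: the expression
compendium is a tab-delimited matrix with a header row of gene identifiers
and one row per experiment (chip); the transcription-factor list is one
identifier per line; the gold standard and prediction lists are tab-delimited
``regulator<TAB>target[<TAB>label-or-score]`` rows.

Identifier matching is exact and case-sensitive throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "RegulatorSet",
    "CandidateEdgeSet",
    "GoldStandard",
    "RankedEdgeList",
    "FormatError",
    "IdentifierError",
    "read_expression",
    "read_tf_list",
    "standardize",
    "build_candidates",
    "read_gold_standard",
    "write_ranked_edges",
    "read_ranked_edges",
]


class FormatError(ValueError):
    """Malformed input file (ragged rows, non-numeric cells, ...)."""


class IdentifierError(ValueError):
    """Unknown or duplicate gene identifier."""


@dataclass
class ExpressionMatrix:
    """An n-experiments x p-genes expression table.

    ``values[i, j]`` is the expression of gene ``gene_ids[j]`` in experiment
    ``i``.  ``standardized`` records whether each gene column has been
    mean-centered and scaled to unit variance.
    """

    values: np.ndarray
    gene_ids: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-d matrix")
        if self.values.shape[1] != len(self.gene_ids):
            raise FormatError(
                f"{self.values.shape[1]} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise IdentifierError("duplicate gene identifiers")
        if not np.isfinite(self.values).all():
            raise FormatError("expression matrix contains non-finite entries")

    @property
    def n_experiments(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def column(self, gene_id: str) -> np.ndarray:
        return self.values[:, self.gene_ids.index(gene_id)]


@dataclass
class RegulatorSet:
    """The designated candidate regulators (transcription factors).

    Per-target candidate sets exclude the target itself: a TF is never a
    candidate regulator of its own expression (no self-regulation).
    """

    gene_ids: list[str]
    tf_ids: list[str]

    def __post_init__(self) -> None:
        known = set(self.gene_ids)
        unknown = [t for t in self.tf_ids if t not in known]
        if unknown:
            raise IdentifierError(f"TF ids not in gene list: {unknown[:5]}")
        if len(set(self.tf_ids)) != len(self.tf_ids):
            raise IdentifierError("duplicate TF identifiers")

    @property
    def n_tfs(self) -> int:
        return self.tf_ids.__len__()

    def candidates_for(self, gene_id: str) -> list[str]:
        """Candidate regulators of ``gene_id`` (all TFs except itself)."""
        return [t for t in self.tf_ids if t != gene_id]


@dataclass
class CandidateEdgeSet:
    """All candidate directed regulations (tf, target), self-pairs excluded."""

    edges: list[tuple[str, str]]
    _edge_set: set[tuple[str, str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._edge_set = set(self.edges)

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._edge_set

    def __iter__(self):
        return iter(self.edges)


@dataclass
class GoldStandard:
    """Verified directed regulations resolved against a candidate universe."""

    positive_edges: set[tuple[str, str]]
    universe: CandidateEdgeSet
    negative_edges: set[tuple[str, str]] | None = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not self.positive_edges:
            raise FormatError("gold standard contains no positive interactions")

    @property
    def n_positives(self) -> int:
        return len(self.positive_edges)

    def evaluation_universe(self) -> list[tuple[str, str]]:
        """Pairs over which confusion counts are defined.

        The full candidate set by default; when an explicit negative set was
        given, only the labelled pairs.
        """
        if self.negative_edges is not None:
            labelled = self.positive_edges | self.negative_edges
            return [e for e in self.universe if e in labelled]
        return list(self.universe)


@dataclass
class RankedEdgeList:
    """Predicted regulations sorted by non-increasing score.

    Ties are broken by lexicographic (regulator, target) so that output
    files are bit-reproducible.
    """

    rows: list[tuple[str, str, float]]

    @classmethod
    def from_unsorted(cls, rows) -> "RankedEdgeList":
        ordered = sorted(rows, key=lambda r: (-r[2], r[0], r[1]))
        return cls(ordered)

    def __post_init__(self) -> None:
        scores = [r[2] for r in self.rows]
        if any(not np.isfinite(s) for s in scores):
            raise FormatError("edge scores must be finite")
        if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
            raise FormatError("ranked edge list not sorted by non-increasing score")
        pairs = [(r[0], r[1]) for r in self.rows]
        if len(set(pairs)) != len(pairs):
            raise FormatError("duplicate (regulator, target) pair in ranked list")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def pairs(self) -> list[tuple[str, str]]:
        return [(r, t) for r, t, _ in self.rows]

    def head(self, k: int) -> "RankedEdgeList":
        return RankedEdgeList(self.rows[:k])


def read_expression(path) -> ExpressionMatrix:
    """Read a DREAM-style tab-delimited expression matrix.

    First row: gene identifiers.  Each subsequent row: one experiment's
    numeric expression values, one column per gene.
    """
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty file")
        gene_ids = header.rstrip("\n").split("\t")
        if len(set(gene_ids)) != len(gene_ids):
            raise IdentifierError(f"{path}: duplicate gene identifier in header")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(gene_ids):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(gene_ids)} fields, got {len(fields)}"
                )
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return ExpressionMatrix(np.array(rows, dtype=float), gene_ids, standardized=False)


def read_tf_list(path) -> list[str]:
    """Read a plain-text TF list, one identifier per line."""
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if len(set(ids)) != len(ids):
        raise IdentifierError(f"{path}: duplicate TF identifier")
    return ids


def standardize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Mean-center each gene and scale to unit variance (1/n denominator).

    Uses the population variance convention (as sklearn's StandardScaler
    does); the choice of denominator does not affect LARS entry orders and
    hence leaves every downstream ranking unchanged.  Constant genes (zero
    variance) are mapped to all-zero columns; a flat probe carries no
    regulatory signal and a zero column can never enter a LARS path.
    Idempotent up to floating-point tolerance.
    """
    V = X.values - X.values.mean(axis=0, keepdims=True)
    sd = V.std(axis=0, ddof=0, keepdims=True)
    nonconst = sd > 0
    V = np.divide(V, sd, out=V, where=nonconst)
    V[:, ~nonconst.ravel()] = 0.0
    return replace(X, values=V, standardized=True)


def build_candidates(
    gene_ids: list[str], tf_ids: list[str] | None = None
) -> tuple[RegulatorSet, CandidateEdgeSet]:
    """Enumerate the candidate regulation universe.

    When ``tf_ids`` is None every gene is a candidate regulator
    (directionality mode, as on networks where the TFs are not known).
    Self-regulations are never candidates, so |E| = q*p - q.
    """
    if tf_ids is None:
        tf_ids = list(gene_ids)
    regs = RegulatorSet(list(gene_ids), list(tf_ids))
    edges = [(t, g) for g in gene_ids for t in tf_ids if t != g]
    return regs, CandidateEdgeSet(edges)


def read_gold_standard(path, universe: CandidateEdgeSet) -> GoldStandard:
    """Read a DREAM-style gold standard: ``regulator target [0/1 label]``.

    A missing label means positive.  Rows whose pair is outside the
    candidate universe (unknown gene, self-edge, non-TF regulator) are
    excluded with a logged count rather than raising: curated gold standards
    routinely contain genes absent from the chip.
    """
    positives: set[tuple[str, str]] = set()
    negatives: set[tuple[str, str]] = set()
    n_excluded = 0
    saw_label = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) not in (2, 3):
                raise FormatError(f"{path}:{lineno}: expected 2 or 3 fields")
            reg, tgt = fields[0], fields[1]
            if (reg, tgt) not in universe:
                n_excluded += 1
                continue
            if len(fields) == 3:
                saw_label = True
                if fields[2] not in ("0", "1"):
                    raise FormatError(f"{path}:{lineno}: label must be 0 or 1")
                (positives if fields[2] == "1" else negatives).add((reg, tgt))
            else:
                positives.add((reg, tgt))
    if n_excluded:
        logger.warning("%s: %d gold-standard rows outside the candidate universe excluded",
                       path, n_excluded)
    return GoldStandard(
        positive_edges=positives,
        universe=universe,
        negative_edges=negatives if saw_label and negatives else None,
        n_excluded=n_excluded,
    )


def write_ranked_edges(ranked: RankedEdgeList, path, max_rows: int | None = None) -> None:
    """Write the DREAM submission format: ``regulator target score``.

    Scores are printed with 6 significant digits; consumers use ranks, not
    the raw floats.
    """
    rows = ranked.rows if max_rows is None else ranked.rows[:max_rows]
    with open(path, "w") as fh:
        for reg, tgt, score in rows:
            fh.write(f"{reg}\t{tgt}\t{score:.6g}\n")


def read_ranked_edges(path) -> RankedEdgeList:
    """Read a prediction list back; validates sortedness and uniqueness."""
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields")
            try:
                rows.append((fields[0], fields[1], float(fields[2])))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric score") from None
    return RankedEdgeList(rows)
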