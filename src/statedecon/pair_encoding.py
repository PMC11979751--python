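"""Within-observation binary relative-expression encoding of gene pairs.

Each feature of the encoding records, for one observation, whether the first
gene of a pair is expressed strictly above the second.  Because the indicator
only depends on the within-observation ordering of two genes, any monotone
per-observation distortion (library size, batch shifts applied uniformly in
log space) leaves the encoding unchanged.  Pairs are pre-filtered to those
whose ordering is maximally undecided across bulk samples (concordance near
0.5), which keeps only pairs that discriminate between samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

DEFAULT_N_TOP = 3000
DEFAULT_LO = 0.49
DEFAULT_HI = 0.51


@dataclass(frozen=True)
class PairList:
    """Canonical ordered gene pairs over a fixed gene list.

    ``index`` is an (n_pairs, 2) integer array of positions into ``genes``;
    for every row the first position is strictly smaller than the second, so
    each unordered pair appears exactly once and self-pairs are excluded.
    """

    genes: tuple[str, ...]
    index: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.index, dtype=np.int64)
        if idx.size == 0:
            idx = idx.reshape(0, 2)
        if idx.ndim != 2 or idx.shape[1] != 2:
            raise ValueError("pair index must be an (n, 2) array")
        if np.any(idx[:, 0] >= idx[:, 1]):
            raise ValueError("pairs must be canonically ordered with no self-pairs")
        object.__setattr__(self, "index", idx)

    def __len__(self) -> int:
        return int(self.index.shape[0])

    def __iter__(self) -> Iterator[tuple[str, str]]:
        for a, b in self.index:
            yield (self.genes[a], self.genes[b])

    def names(self) -> list[tuple[str, str]]:
        return list(self)

    def labels(self) -> list[str]:
        return [f"{a}|{b}" for a, b in self]

    def subset(self, keep: np.ndarray) -> "PairList":
        return PairList(self.genes, self.index[keep])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PairList):
            return NotImplemented
        return self.genes == other.genes and np.array_equal(self.index, other.index)


@dataclass
class RelativeEncoding:
    """Fitted encoding: gene universe, variability scores and filtered pairs."""

    shared_genes: list[str]
    selected_genes: list[str]
    scores: pd.Series
    pairs: PairList
    concordance: np.ndarray
    n_top: int
    bounds: tuple[float, float]


@dataclass
class BinaryRelativeMatrix:
    """Observation x pair binary matrix produced by :func:`encode_relative`."""

    values: np.ndarray  # (n_obs, n_pairs) uint8
    observations: list[str]
    pairs: PairList
    source_id: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("binary matrix entries must be 0 or 1")
        if vals.shape[1] != len(self.pairs):
            raise ValueError("column count must equal number of pairs")
        self.values = vals.astype(np.uint8)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.observations, columns=self.pairs.labels())


def intersect_genes(sc_genes: Sequence[str], bulk_genes: Sequence[str]) -> list[str]:
    """Genes present in both lists, sorted lexicographically.

    Raises ``ValueError`` if either list is empty or the intersection is empty.
    """
    if not len(sc_genes) or not len(bulk_genes):
        raise ValueError("gene lists must be non-empty")
    shared = sorted(set(sc_genes) & set(bulk_genes))
    if not shared:
        raise ValueError("gene universes do not overlap: empty intersection")
    return shared


def select_variable_genes(
    sc_matrix: ExpressionMatrix, shared: Sequence[str], n_top: int = DEFAULT_N_TOP
) -> pd.Series:
    """Score genes by median absolute deviation across cells and keep the top ``n_top``.

    The per-gene score is median over cells of |expression - per-gene median|.
    Returns a Series of scores indexed by gene, in descending-score order
    (ties broken by gene name for determinism), of length min(n_top, |shared|).
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    sub = sc_matrix.subset_genes(list(shared))
    vals = sub.to_numpy()
    med = np.median(vals, axis=1, keepdims=True)
    mad = np.median(np.abs(vals - med), axis=1)
    scores = pd.Series(mad, index=sub.genes, name="score")
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    return scores.loc[order[: min(n_top, len(order))]]


def enumerate_pairs(selected: Sequence[str]) -> PairList:
    """All unordered pairs of distinct genes, each emitted once in list order."""
    genes = tuple(selected)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to enumerate pairs")
    if len(set(genes)) != len(genes):
        raise ValueError("selected gene list contains duplicates")
    i, j = np.triu_indices(len(genes), k=1)
    return PairList(genes, np.column_stack([i, j]))


def _pair_gene_rows(matrix: ExpressionMatrix, pairs: PairList) -> np.ndarray:
    """Rows of ``matrix`` aligned to ``pairs.genes``; errors name the missing gene."""
    missing = [g for g in pairs.genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"gene not present in matrix: {missing[0]!r}")
    return matrix.values.loc[list(pairs.genes)].to_numpy(dtype=float)


def bulk_concordance(
    bulk: ExpressionMatrix, pairs: PairList, chunk_size: int = 500_000
) -> np.ndarray:
    """Per-pair fraction of bulk samples where gene a strictly exceeds gene b.

    Ties contribute 0.  Computed in chunks over pairs so memory stays bounded;
    results are bit-identical to the dense computation.
    """
    if bulk.n_obs < 1:
        raise ValueError("bulk matrix must have at least one sample")
    vals = _pair_gene_rows(bulk, pairs)  # genes x samples
    n_samples = vals.shape[1]
    idx = pairs.index
    out = np.empty(len(pairs), dtype=float)
    for start in range(0, len(pairs), chunk_size):
        stop = min(start + chunk_size, len(pairs))
        a = vals[idx[start:stop, 0]]
        b = vals[idx[start:stop, 1]]
        out[start:stop] = (a > b).sum(axis=1) / n_samples
    return out


def filter_pairs(
    pairs: PairList,
    concordance: np.ndarray,
    lo: float = DEFAULT_LO,
    hi: float = DEFAULT_HI,
) -> tuple[PairList, np.ndarray]:
    """Retain pairs whose concordance lies in [lo, hi], inclusive both ends."""
    if lo > hi:
        raise ValueError(f"lo ({lo}) must not exceed hi ({hi})")
    concordance = np.asarray(concordance, dtype=float)
    if concordance.shape[0] != len(pairs):
        raise ValueError("concordance length must match pair count")
    keep = (concordance >= lo) & (concordance <= hi)
    return pairs.subset(keep), concordance[keep]


def encode_relative(
    matrix: ExpressionMatrix, pairs: PairList, source_id: str = ""
) -> BinaryRelativeMatrix:
    """Binary matrix: entry 1 iff the pair's first gene strictly exceeds its second.

    Applies identically to single-cell and bulk matrices; ties encode as 0.
    """
    vals = _pair_gene_rows(matrix, pairs)
    idx = pairs.index
    binary = (vals[idx[:, 0]] > vals[idx[:, 1]]).T.astype(np.uint8)
    return BinaryRelativeMatrix(binary, matrix.observations, pairs, source_id=source_id)


def fit_encoding(
    sc_matrix: ExpressionMatrix,
    bulk_matrix: ExpressionMatrix,
    n_top: int = DEFAULT_N_TOP,
    lo: float = DEFAULT_LO,
    hi: float = DEFAULT_HI,
) -> RelativeEncoding:
    """Full encoding pipeline: intersect, select variable genes, enumerate and filter pairs."""
    shared = intersect_genes(sc_matrix.genes, bulk_matrix.genes)
    scores = select_variable_genes(sc_matrix, shared, n_top=n_top)
    selected = list(scores.index)
    pairs = enumerate_pairs(selected)
    conc = bulk_concordance(bulk_matrix, pairs)
    kept, kept_conc = filter_pairs(pairs, conc, lo=lo, hi=hi)
    if len(kept) == 0:
        raise ValueError(
            f"no pairs retained with concordance in [{lo}, {hi}]; "
            f"with {bulk_matrix.n_obs} bulk samples concordance is quantized to "
            f"multiples of 1/{bulk_matrix.n_obs} - widen the bounds or change "
            "the bulk sample count"
        )
    return RelativeEncoding(
        shared_genes=shared,
        selected_genes=selected,
        scores=scores,
        pairs=kept,
        concordance=kept_conc,
        n_top=n_top,
        bounds=(lo, hi),
    )
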