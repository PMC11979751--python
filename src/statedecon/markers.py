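"""State-marker selection via detection-fraction specificity distance.

A gene's detection vector (fraction of cells with expression > 0 per state)
is compared against the one-hot indicator of a target state by cosine
similarity; the specificity distance is one minus that similarity, so 0 means
the gene is detected only in the target state and 1 means it is never
detected there but is elsewhere.  Genes falling in the lowest-mean-distance
k-means group per state are ranked by fold-change and capped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .matrix import ExpressionMatrix

DEFAULT_TOP_N = 80
DEFAULT_N_GROUPS = 10
DEFAULT_DISCORDANCE_TOP_N = 500
_FOLD_EPS = 1e-9


@dataclass
class SpecificityTable:
    detection: pd.DataFrame  # gene x state detection fractions
    sd: pd.DataFrame  # gene x state specificity distance
    undetected: pd.Series  # genes whose detection vector is all zero (sd forced to 1)


@dataclass
class MarkerSet:
    """Per-state ordered marker genes with fold-change and specificity distance."""

    table: pd.DataFrame  # columns: state, gene, fold_change, sd
    top_n: int
    n_groups: int
    seed: int

    def genes_for(self, state: str) -> list[str]:
        return list(self.table.loc[self.table["state"] == state, "gene"])

    @property
    def states(self) -> list[str]:
        return sorted(self.table["state"].unique())

    def all_genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())


def detection_fractions(matrix: ExpressionMatrix, labels: pd.Series) -> pd.DataFrame:
    """Per gene and state, the fraction of that state's cells with expression > 0."""
    labels = labels.reindex(matrix.observations)
    if labels.isna().any():
        raise ValueError("labels missing for some observations")
    states = sorted(labels.unique())
    out = {}
    for state in states:
        cols = labels.index[labels == state]
        if len(cols) == 0:
            raise ValueError(f"state {state!r} has no cells")
        out[state] = (matrix.values[cols].to_numpy() > 0).mean(axis=1)
    return pd.DataFrame(out, index=matrix.genes)


def specificity_distance(detection_row: np.ndarray, state: int) -> float:
    """1 - cosine similarity between a detection vector and the one-hot state indicator.

    An all-zero detection vector is maximally non-specific by convention
    (distance 1); the cosine is 0/0 there.
    """
    u = np.asarray(detection_row, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise ValueError("detection fractions must lie in [0, 1]")
    norm = np.linalg.norm(u)
    if norm == 0:
        return 1.0
    return float(1.0 - u[state] / norm)


def specificity_table(matrix: ExpressionMatrix, labels: pd.Series) -> SpecificityTable:
    """Detection fractions and specificity distances for every gene and state."""
    det = detection_fractions(matrix, labels)
    vals = det.to_numpy()
    norms = np.linalg.norm(vals, axis=1)
    undetected = norms == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = 1.0 - vals / norms[:, None]
    sd[undetected] = 1.0
    return SpecificityTable(
        detection=det,
        sd=pd.DataFrame(sd, index=det.index, columns=det.columns),
        undetected=pd.Series(undetected, index=det.index, name="undetected"),
    )


def _lowest_sd_group(sd_values: np.ndarray, n_groups: int, seed: int) -> np.ndarray:
    """Boolean mask of genes in the k-means group with the lowest mean distance."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*distinct clusters.*")
        km = KMeans(n_clusters=n_groups, n_init=10, random_state=seed)
        assignment = km.fit_predict(sd_values.reshape(-1, 1))
    means = [
        sd_values[assignment == g].mean() if (assignment == g).any() else np.inf
        for g in range(n_groups)
    ]
    best = int(np.argmin(means))
    return assignment == best


def select_markers(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    top_n: int = DEFAULT_TOP_N,
    n_groups: int = DEFAULT_N_GROUPS,
    seed: int = 0,
) -> MarkerSet:
    """Per state: group genes by 1-D k-means on specificity distance, keep the
    lowest-distance group and return up to ``top_n`` of its genes by fold-change.

    Fold-change is computed on linear TPM values (log reversed) as
    (state mean + eps) / (rest mean + eps).
    """
    if matrix.n_genes < n_groups:
        raise ValueError(
            f"need at least n_groups ({n_groups}) genes, have {matrix.n_genes}"
        )
    spec = specificity_table(matrix, labels)
    labels = labels.reindex(matrix.observations)
    tpm = np.exp2(matrix.to_numpy()) - 1.0 if matrix.space == "logTPM" else matrix.to_numpy()
    genes = np.asarray(matrix.genes)

    rows = []
    for state in spec.sd.columns:
        sd_vec = spec.sd[state].to_numpy()
        in_group = _lowest_sd_group(sd_vec, n_groups, seed)
        cols = np.asarray([o in set(labels.index[labels == state]) for o in matrix.observations])
        fc = (tpm[:, cols].mean(axis=1) + _FOLD_EPS) / (tpm[:, ~cols].mean(axis=1) + _FOLD_EPS)
        cand = pd.DataFrame(
            {
                "state": state,
                "gene": genes[in_group],
                "fold_change": fc[in_group],
                "sd": sd_vec[in_group],
            }
        )
        cand = cand.sort_values(["fold_change", "gene"], ascending=[False, True], kind="stable")
        rows.append(cand.head(top_n))
    table = pd.concat(rows, ignore_index=True)
    return MarkerSet(table=table, top_n=top_n, n_groups=n_groups, seed=seed)


def discordance_select(
    de_table: pd.DataFrame,
    rts: pd.Series,
    top_n: int = DEFAULT_DISCORDANCE_TOP_N,
) -> pd.DataFrame:
    """Rank upregulated genes by repressive-tendency score x rank-sum location shift.

    ``de_table`` is the one-state slice of a differential-expression table with
    ``gene``, ``location`` and ``direction`` columns.  Genes without a
    repressive-tendency score are excluded.  Returns up to ``top_n`` rows
    ordered by descending score.
    """
    up = de_table[de_table["direction"] == "up"].copy()
    if up.empty:
        warnings.warn("no upregulated genes; discordance selection is empty")
        return pd.DataFrame(columns=["gene", "location", "rts", "score"])
    up["rts"] = up["gene"].map(rts)
    up = up.dropna(subset=["rts"])
    up["score"] = up["rts"] * up["location"]
    up = up.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    return up[["gene", "location", "rts", "score"]].head(top_n).reset_index(drop=True)
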