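"""Trajectory fitting on the binary relative-expression matrix.

Cells are clustered by complete-linkage hierarchical clustering on Euclidean
distances between their binary pair profiles; PCA on the same matrix gives the
trajectory coordinates, and external datasets encoded on the same pair list
are projected into that space by centering with the training means and taking
dot products with the component weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .matrix import ExpressionMatrix
from .pair_encoding import BinaryRelativeMatrix, PairList

_EXACT_MAX_N = 25  # exact rank-sum distribution up to this group size


@dataclass
class TrajectoryModel:
    components: np.ndarray  # (n_components, n_pairs)
    training_means: np.ndarray  # (n_pairs,)
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    pairs: PairList
    cluster_labels: pd.Series | None = None
    n_clusters: int | None = None
    linkage: str = "complete"
    training_coordinates: pd.DataFrame | None = None


def cluster_cells(binary: BinaryRelativeMatrix, n_clusters: int) -> pd.Series:
    """Cut a complete-linkage Euclidean dendrogram of cells into ``n_clusters`` states."""
    n = binary.values.shape[0]
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > n:
        raise ValueError(f"n_clusters ({n_clusters}) exceeds number of observations ({n})")
    Z = linkage(binary.values.astype(float), method="complete", metric="euclidean")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    # relabel in order of first appearance for determinism
    remap: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap) + 1
        labels.append(f"S{remap[r]}")
    return pd.Series(labels, index=binary.observations, name="state")


def fit_pca(
    binary: BinaryRelativeMatrix,
    n_components: int,
    cluster_labels: pd.Series | None = None,
) -> TrajectoryModel:
    """Mean-centered PCA of the training binary matrix."""
    X = binary.values.astype(float)
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components ({n_components}) exceeds min(n_obs, n_pairs) = {min(X.shape)}"
        )
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("binary matrix has zero variance in every column")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    model = TrajectoryModel(
        components=pca.components_,
        training_means=pca.mean_,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        pairs=binary.pairs,
        cluster_labels=cluster_labels,
        n_clusters=None if cluster_labels is None else cluster_labels.nunique(),
        training_coordinates=pd.DataFrame(
            coords,
            index=binary.observations,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
    )
    return model


def project(model: TrajectoryModel, binary: BinaryRelativeMatrix) -> pd.DataFrame:
    """Coordinates of new observations: (values - training_means) . components^T."""
    if binary.pairs != model.pairs:
        for got, exp in zip(binary.pairs.names(), model.pairs.names()):
            if got != exp:
                raise ValueError(f"pair list mismatch: got {got}, model expects {exp}")
        raise ValueError(
            f"pair list mismatch: model has {len(model.pairs)} pairs, "
            f"matrix has {len(binary.pairs)}"
        )
    coords = (binary.values.astype(float) - model.training_means) @ model.components.T
    return pd.DataFrame(
        coords,
        index=binary.observations,
        columns=[f"PC{i + 1}" for i in range(model.components.shape[0])],
    )


def _rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test for one gene.

    Exact null distribution for small tie-free groups, otherwise the normal
    approximation with tie and continuity corrections.
    """
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if len(x) <= _EXACT_MAX_N and len(y) <= _EXACT_MAX_N and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def de_one_vs_rest(
    matrix: ExpressionMatrix, labels: pd.Series, test: str = "wilcoxon"
) -> pd.DataFrame:
    """One-versus-rest differential expression per gene per state.

    Returns a long-format table with Bonferroni adjustment across all
    (gene, state) tests and ``location`` = mean(state) - mean(rest).
    """
    if test not in ("wilcoxon", "ttest"):
        raise ValueError(f"test must be 'wilcoxon' or 'ttest', got {test!r}")
    labels = labels.reindex(matrix.observations)
    if labels.isna().any():
        raise ValueError("labels missing for some observations")
    states = sorted(labels.unique())
    if len(states) < 2:
        raise ValueError("need at least 2 states")
    counts = labels.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"state {small.index[0]!r} has fewer than 2 observations")

    vals = matrix.to_numpy()
    obs_idx = {o: i for i, o in enumerate(matrix.observations)}
    n_tests = matrix.n_genes * len(states)
    rows = []
    for state in states:
        in_state = np.array([obs_idx[o] for o in labels.index[labels == state]])
        in_rest = np.array([obs_idx[o] for o in labels.index[labels != state]])
        xs, ys = vals[:, in_state], vals[:, in_rest]
        loc = xs.mean(axis=1) - ys.mean(axis=1)
        if test == "ttest":
            res = stats.ttest_ind(xs, ys, axis=1)
            stat_vec, p_vec = np.asarray(res.statistic), np.asarray(res.pvalue)
            p_vec = np.where(np.isnan(p_vec), 1.0, p_vec)
            for g, gene in enumerate(matrix.genes):
                rows.append((gene, state, stat_vec[g], p_vec[g], loc[g]))
        else:
            for g, gene in enumerate(matrix.genes):
                x, y = xs[g], ys[g]
                if np.all(x == x[0]) and np.all(y == x[0]):
                    stat, p = len(x) * len(y) / 2.0, 1.0
                else:
                    stat, p = _rank_sum_test(x, y)
                rows.append((gene, state, stat, p, loc[g]))
    out = pd.DataFrame(rows, columns=["gene", "state", "statistic", "p", "location"])
    out["p_adj"] = np.minimum(1.0, out["p"] * n_tests)
    out["direction"] = np.where(out["location"] > 0, "up", np.where(out["location"] < 0, "down", "none"))
    out["significant"] = out["p_adj"] < 0.05
    return out


def pc_gene_correlation(
    matrix: ExpressionMatrix, coordinates: pd.DataFrame, component: str | int = "PC1"
) -> pd.DataFrame:
    """Spearman correlation of every gene with one PC, ranked most positive first.

    Only genes significant after Bonferroni correction (adjusted p < 0.05) are
    returned; the table is suitable for export as a preranked gene list.
    """
    if isinstance(component, int):
        component = f"PC{component}"
    pc = coordinates[component].reindex(matrix.observations).to_numpy(dtype=float)
    if np.isnan(pc).any():
        raise ValueError("coordinates missing for some observations")
    if np.all(pc == pc[0]):
        raise ValueError("constant PC vector: correlation undefined")

    vals = matrix.to_numpy()
    n = vals.shape[1]
    rank_pc = stats.rankdata(pc)
    rank_genes = stats.rankdata(vals, axis=1)
    rg = rank_genes - rank_genes.mean(axis=1, keepdims=True)
    rp = rank_pc - rank_pc.mean()
    denom = np.sqrt((rg**2).sum(axis=1) * (rp**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rg @ rp) / denom
    # t-approximation, as in scipy.stats.spearmanr
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    out = pd.DataFrame({"gene": matrix.genes, "rho": rho, "p": p})
    out = out.dropna(subset=["rho"])
    out["p_adj"] = np.minimum(1.0, out["p"] * matrix.n_genes)
    out = out[out["p_adj"] < 0.05]
    return out.sort_values(["rho", "gene"], ascending=[False, True]).reset_index(drop=True)


def crosstab_state_proportions(labels_a: pd.Series, labels_joint: pd.Series) -> pd.DataFrame:
    """Fraction of each state's cells falling in each joint cluster; rows sum to 1."""
    if len(labels_a) != len(labels_joint):
        raise ValueError(
            f"label vectors differ in length: {len(labels_a)} vs {len(labels_joint)}"
        )
    return pd.crosstab(
        pd.Series(np.asarray(labels_a), name="state"),
        pd.Series(np.asarray(labels_joint), name="joint"),
        normalize="index",
    )
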