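"""Signed drug-signature matrix, similarity graph clustering and susceptibility summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd

DEFAULT_K = 15
DEFAULT_RESOLUTION = 2.95


@dataclass
class DrugSignatureSet:
    """Per-drug up/down gene lists over a shared gene universe."""

    up: dict[str, list[str]]
    down: dict[str, list[str]]
    universe: list[str]
    moa: dict[str, str] = field(default_factory=dict)
    targets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.up) != set(self.down):
            raise ValueError("up and down signature dicts must cover the same drugs")
        uni = set(self.universe)
        for drug in self.up:
            overlap = set(self.up[drug]) & set(self.down[drug])
            if overlap:
                raise ValueError(
                    f"drug {drug!r}: gene {sorted(overlap)[0]!r} in both up and down sets"
                )
            stray = (set(self.up[drug]) | set(self.down[drug])) - uni
            if stray:
                raise ValueError(f"drug {drug!r}: gene {sorted(stray)[0]!r} not in universe")

    @property
    def drugs(self) -> list[str]:
        return sorted(self.up)


@dataclass
class DrugGraph:
    """k-nearest-neighbor graph over drugs under normalized hamming distance."""

    drugs: list[str]
    neighbors: dict[str, list[tuple[str, float]]]  # symmetrized adjacency with distances
    graph: ig.Graph
    k: int
    cluster_labels: pd.Series | None = None
    embedding: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)


@dataclass
class SensitivityTable:
    """Drug x (study, state) susceptibility scores with a recorded binarization rule."""

    scores: pd.DataFrame  # drugs x (study, state) columns
    flags: pd.DataFrame  # same shape, bool: "predicted to target"
    rule: str


def build_sign_matrix(signatures: DrugSignatureSet) -> pd.DataFrame:
    """Drug x gene matrix over {-1, 0, 1}: 1 for up-regulated, -1 for down, 0 otherwise."""
    universe = list(signatures.universe)
    pos = {g: i for i, g in enumerate(universe)}
    drugs = signatures.drugs
    mat = np.zeros((len(drugs), len(universe)), dtype=np.int8)
    for r, drug in enumerate(drugs):
        for g in signatures.up[drug]:
            mat[r, pos[g]] = 1
        for g in signatures.down[drug]:
            mat[r, pos[g]] = -1
    return pd.DataFrame(mat, index=drugs, columns=universe)


def hamming_distance_matrix(D: pd.DataFrame) -> pd.DataFrame:
    """All-pairs normalized hamming distance: fraction of positions with unequal symbols."""
    vals = D.to_numpy()
    n = vals.shape[0]
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        out[i] = (vals != vals[i]).mean(axis=1)
    return pd.DataFrame(out, index=D.index, columns=D.index)


def drug_similarity_graph(D: pd.DataFrame, k: int = DEFAULT_K) -> DrugGraph:
    """Symmetrized (union) kNN graph under normalized hamming distance.

    ``D`` is the signed drug x gene matrix.  Edges carry the distance; Leiden
    clustering later uses similarity weights 1 - distance.
    """
    n = D.shape[0]
    if n < 1:
        raise ValueError("need at least one drug")
    if k >= n and not (n == 1 and k == 0):
        raise ValueError(f"k ({k}) must be smaller than the number of drugs ({n})")
    drugs = list(D.index)
    dist = hamming_distance_matrix(D).to_numpy()

    edges: dict[tuple[int, int], float] = {}
    for i in range(n):
        if k > 0:
            order = np.argsort(dist[i], kind="stable")
            nearest = [j for j in order if j != i][:k]
            for j in nearest:
                key = (min(i, j), max(i, j))
                edges[key] = dist[i, j]

    graph = ig.Graph(n=n, edges=list(edges.keys()), directed=False)
    graph.vs["name"] = drugs
    graph.es["distance"] = list(edges.values())
    graph.es["weight"] = [1.0 - d for d in edges.values()]

    neighbors: dict[str, list[tuple[str, float]]] = {d: [] for d in drugs}
    for (i, j), d in edges.items():
        neighbors[drugs[i]].append((drugs[j], d))
        neighbors[drugs[j]].append((drugs[i], d))
    for d in neighbors:
        neighbors[d].sort(key=lambda t: (t[1], t[0]))
    return DrugGraph(drugs=drugs, neighbors=neighbors, graph=graph, k=k, params={"k": k})


def cluster_drugs(
    graph: DrugGraph, resolution: float = DEFAULT_RESOLUTION, seed: int = 0
) -> pd.Series:
    """Leiden community detection on the drug graph at the given resolution."""
    if not graph.drugs:
        raise ValueError("empty drug graph")
    weights = graph.graph.es["weight"] if graph.graph.ecount() else None
    part = leidenalg.find_partition(
        graph.graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = pd.Series(part.membership, index=graph.drugs, name="cluster")
    graph.cluster_labels = labels
    graph.params.update({"resolution": resolution, "seed": seed})
    return labels


def embed_drugs(graph: DrugGraph, D: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """2-D UMAP layout of drugs under the hamming metric; deterministic for a seed."""
    import umap  # deferred: heavy import

    n = D.shape[0]
    if n == 1:
        coords = pd.DataFrame([[0.0, 0.0]], index=D.index, columns=["x", "y"])
    else:
        reducer = umap.UMAP(
            n_components=2,
            metric="hamming",
            n_neighbors=min(DEFAULT_K, n - 1),
            random_state=seed,
        )
        emb = reducer.fit_transform(D.to_numpy())
        coords = pd.DataFrame(emb, index=D.index, columns=["x", "y"])
    graph.embedding = coords
    graph.params["embed_seed"] = seed
    return coords


def flag_targets(scores: pd.DataFrame, top_n: int = 10) -> SensitivityTable:
    """Binarize susceptibility scores: per (study, state) column, flag the top-N drugs.

    Lower BeyondCell-style residual means indicate stronger predicted
    susceptibility in some conventions; here larger score = more susceptible,
    so callers should orient scores accordingly.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    flags = pd.DataFrame(False, index=scores.index, columns=scores.columns)
    for col in scores.columns:
        top = scores[col].sort_values(ascending=False, kind="stable").index[:top_n]
        flags.loc[top, col] = True
    return SensitivityTable(scores=scores, flags=flags, rule=f"top_{top_n}_per_state")


def overlap_matrix(sens: SensitivityTable) -> pd.DataFrame:
    """Symmetric (study,state) x (study,state) matrix of shared flagged drugs.

    Diagonal entries count each column's own flagged drugs.
    """
    flags = sens.flags.to_numpy(dtype=int)
    overlap = flags.T @ flags
    return pd.DataFrame(overlap, index=sens.flags.columns, columns=sens.flags.columns)


def rank_drugs_by_states(sens: SensitivityTable) -> pd.Series:
    """Per drug, the number of (study, state) columns it is flagged to target.

    Descending by count, ties broken by drug identifier.
    """
    counts = sens.flags.sum(axis=1).astype(int)
    order = sorted(counts.index, key=lambda d: (-counts[d], d))
    return counts.loc[order]


def target_expression_summary(
    datasets: list[tuple[str, "ExpressionMatrix", pd.Series]],
    target_genes: dict[str, list[str]],
    detection_threshold: float = 0.1,
    invasive_label: str = "invasive",
) -> pd.DataFrame:
    """Mean expression and detection fraction of drug-target genes per dataset and state.

    ``datasets`` holds (name, matrix, per-cell state labels) triples.  The
    ``consistent`` flag marks genes detected above ``detection_threshold`` in
    the invasive-labelled state of every dataset; genes absent from any
    dataset are reported with null values and flagged inconsistent.
    """
    rows = []
    consistent: dict[tuple[str, str], bool] = {}
    for cluster, genes in target_genes.items():
        for gene in genes:
            ok = True
            for name, matrix, labels in datasets:
                labels = labels.reindex(matrix.observations)
                present = gene in matrix.values.index
                seen_invasive = False
                for state in sorted(labels.dropna().unique()):
                    cols = labels.index[labels == state]
                    if present:
                        vals = matrix.values.loc[gene, cols].to_numpy()
                        mean = float(vals.mean())
                        det = float((vals > 0).mean())
                    else:
                        mean, det = np.nan, np.nan
                    rows.append(
                        {
                            "cluster": cluster,
                            "gene": gene,
                            "dataset": name,
                            "state": state,
                            "mean_expression": mean,
                            "detection_fraction": det,
                        }
                    )
                    if state == invasive_label and present and det > detection_threshold:
                        seen_invasive = True
                if not seen_invasive:
                    ok = False
            consistent[(cluster, gene)] = ok
    out = pd.DataFrame(rows)
    if not out.empty:
        out["consistent"] = [
            consistent[(c, g)] for c, g in zip(out["cluster"], out["gene"])
        ]
    return out
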