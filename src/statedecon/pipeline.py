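"""End-to-end orchestration of the synthetic analysis pipeline.

Runs simulate -> encode -> trajectory -> markers -> deconvolve -> impute ->
drugs -> enrich in dependency order, writing every stage output plus the
resolved configuration next to the artifacts so a rerun is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .deconvolution import build_signature, deconvolve_matrix, impute_state_expression
from .drugs import (
    build_sign_matrix,
    cluster_drugs,
    drug_similarity_graph,
    flag_targets,
    overlap_matrix,
    rank_drugs_by_states,
)
from .enrichment import GeneSetCollection, fisher_enrichment
from .markers import select_markers
from .pair_encoding import encode_relative, fit_encoding
from .syndata import SyntheticConfig, simulate_bulk, simulate_drug_signatures, simulate_states
from .trajectory import cluster_cells, de_one_vs_rest, fit_pca, project


@dataclass
class PipelineConfig:
    """Resolved parameters for every stage; round-trips through YAML."""

    # synthetic data
    n_states: int = 4
    n_genes: int = 600
    markers_per_state: int = 40
    n_cells_per_state: int = 60
    n_bulk_samples: int = 30
    marker_effect: float = 4.0
    noise_sd: float = 0.4
    dropout_rate: float = 0.2
    n_patients: int = 3
    batch_sd: float = 0.3
    bulk_noise_sd: float = 0.1
    # encoding
    n_top: int = 200
    lo: float = 0.49
    hi: float = 0.51
    # trajectory
    n_clusters: int = 4
    n_components: int = 5
    # markers
    marker_top_n: int = 80
    marker_n_groups: int = 10
    # deconvolution
    nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75)
    alpha: float = 1e-4
    # drugs
    n_drug_classes: int = 4
    drugs_per_class: int = 8
    genes_per_signature: int = 40
    flip_rate: float = 0.02
    knn_k: int = 10
    resolution: float = 2.95
    flag_top_n: int = 10
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["nu_grid"] = list(self.nu_grid)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if "nu_grid" in payload:
            payload["nu_grid"] = tuple(payload["nu_grid"])
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(payload) - known
        if stray:
            raise ValueError(f"unknown config fields: {sorted(stray)}")
        return cls(**payload)

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(
            n_states=self.n_states,
            n_genes=self.n_genes,
            markers_per_state=self.markers_per_state,
            n_cells_per_state=self.n_cells_per_state,
            n_bulk_samples=self.n_bulk_samples,
            marker_effect=self.marker_effect,
            noise_sd=self.noise_sd,
            dropout_rate=self.dropout_rate,
            n_patients=self.n_patients,
            batch_sd=self.batch_sd,
            seed=self.seed,
        )


def _drug_sensitivity_scores(D: pd.DataFrame, state_means: pd.DataFrame) -> pd.DataFrame:
    """Synthetic susceptibility scores: drugs down-regulating a state's highly
    expressed genes score high for that state (plumbing for the overlap/rank stage)."""
    genes = [g for g in D.columns if g in state_means.index]
    centered = state_means.loc[genes] - state_means.loc[genes].mean(axis=1).to_numpy()[:, None]
    scores = -(D[genes].to_numpy(dtype=float) @ centered.to_numpy())
    cols = [("synthetic", s) for s in state_means.columns]
    return pd.DataFrame(scores, index=D.index,
                        columns=pd.MultiIndex.from_tuples(cols, names=["study", "state"]))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute every stage on synthetic data and write all artifacts to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    # --- simulate
    sc, truth = simulate_states(config.synthetic_config())
    bulk, proportions = simulate_bulk(
        truth, config.n_bulk_samples, config.bulk_noise_sd, seed=config.seed + 1
    )
    sio.write_expression(sc, outdir / "single_cell.tsv")
    sio.write_expression(bulk, outdir / "bulk.tsv")

    # --- encode
    encoding = fit_encoding(sc, bulk, n_top=config.n_top, lo=config.lo, hi=config.hi)
    sio.write_pairs(encoding.pairs, encoding.concordance, outdir / "pairs.tsv")
    sc_binary = encode_relative(sc, encoding.pairs, source_id="single_cell")
    bulk_binary = encode_relative(bulk, encoding.pairs, source_id="bulk")

    # --- trajectory
    labels = cluster_cells(sc_binary, config.n_clusters)
    model = fit_pca(sc_binary, config.n_components, cluster_labels=labels)
    sio.write_labels(labels, outdir / "cell_states.tsv")
    model.training_coordinates.to_csv(outdir / "cell_coordinates.tsv", sep="\t")
    project(model, bulk_binary).to_csv(outdir / "bulk_coordinates.tsv", sep="\t")

    de = de_one_vs_rest(sc, labels, test="wilcoxon")
    de.to_csv(outdir / "de.tsv", sep="\t", index=False)

    # --- markers
    markers = select_markers(
        sc, labels, top_n=config.marker_top_n, n_groups=config.marker_n_groups,
        seed=config.seed,
    )
    markers.table.to_csv(outdir / "markers.tsv", sep="\t", index=False)
    sio.write_gmt(
        {state: markers.genes_for(state) for state in markers.states},
        outdir / "markers.gmt",
    )

    # --- deconvolution + imputation
    signature = build_signature(sc, labels, markers)
    signature.values.to_csv(outdir / "signature.tsv", sep="\t", index_label="gene")
    estimate = deconvolve_matrix(bulk, signature, nu_grid=config.nu_grid)
    estimate.proportions.to_csv(outdir / "proportions.tsv", sep="\t", index_label="sample")
    imputed = impute_state_expression(
        bulk.subset_genes(signature.genes), estimate, alpha=config.alpha
    )
    imputed.values.to_csv(outdir / "imputed_expression.tsv", sep="\t", index_label="gene")

    # --- drugs
    signatures = simulate_drug_signatures(
        config.n_drug_classes, config.drugs_per_class, config.genes_per_signature,
        universe=sc.genes, flip_rate=config.flip_rate, seed=config.seed + 2, truth=truth,
    )
    sio.write_drug_signatures(signatures, outdir / "drug_signatures.json")
    sio.write_ground_truth(truth, outdir / "ground_truth.json")
    D = build_sign_matrix(signatures)
    graph = drug_similarity_graph(D, k=min(config.knn_k, D.shape[0] - 1))
    clusters = cluster_drugs(graph, resolution=config.resolution, seed=config.seed)
    clusters.to_csv(outdir / "drug_clusters.tsv", sep="\t", index_label="drug")
    sens = flag_targets(_drug_sensitivity_scores(D, truth.state_means), top_n=config.flag_top_n)
    overlap_matrix(sens).to_csv(outdir / "drug_overlap.tsv", sep="\t")
    rank_drugs_by_states(sens).rename("n_states").to_csv(
        outdir / "drug_rank.tsv", sep="\t", index_label="drug"
    )

    # --- enrichment: markers of each state against the generating marker sets
    collection = GeneSetCollection({f"truth_{s}": set(g) for s, g in truth.marker_genes.items()})
    enrich = fisher_enrichment(markers.genes_for(markers.states[0]), collection, sc.genes)
    enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    manifest = {p.name: p.stat().st_size for p in sorted(outdir.iterdir())}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
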