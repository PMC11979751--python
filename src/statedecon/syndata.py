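"""Ground-truthed synthetic inputs for every downstream stage.

The generator works in log2(TPM+1) space.  Noiseless per-state gene means are
drawn once; marker genes get a fold-change elevation in their own state.
Single cells add per-patient batch shifts, Gaussian noise and Bernoulli
dropout.  Bulk samples are proportion-weighted mixtures of the state mean
profiles formed in linear TPM space (physical mixtures average linear
abundances) and then log-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drugs import DrugSignatureSet
from .matrix import ExpressionMatrix

# Marker genes get a low baseline so that, outside their own state, they often
# fall below the detection limit; this creates the state-specific
# detection-fraction structure the specificity distance relies on.
_MARKER_BASELINE = (0.2, 0.8)
_NONMARKER_BASELINE = (1.0, 6.0)
# Single-cell log values below this detection limit read as zero (applied
# after noise, before dropout).
_DETECTION_FLOOR = 0.6


@dataclass
class SyntheticConfig:
    n_states: int = 4
    n_genes: int = 1000
    markers_per_state: int = 50
    n_cells_per_state: int = 100
    n_bulk_samples: int = 30
    marker_effect: float = 4.0
    noise_sd: float = 0.5
    dropout_rate: float = 0.2
    n_patients: int = 4
    batch_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_states", "n_genes", "markers_per_state", "n_cells_per_state",
                     "n_bulk_samples", "n_patients"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.markers_per_state * self.n_states > self.n_genes:
            raise ValueError(
                "markers_per_state x n_states exceeds n_genes "
                f"({self.markers_per_state} x {self.n_states} > {self.n_genes})"
            )
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        for name in ("marker_effect", "noise_sd", "batch_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")


@dataclass
class GroundTruth:
    """Generating quantities for verifying downstream estimates."""

    state_of_cell: pd.Series  # cell id -> state label
    state_means: pd.DataFrame  # gene x state, noiseless log2(TPM+1)
    marker_genes: dict[str, list[str]]
    proportions: pd.DataFrame | None = None  # bulk sample x state
    drug_class_of: dict[str, str] = field(default_factory=dict)
    patient_of_cell: pd.Series | None = None


def simulate_states(config: SyntheticConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate multi-state single-cell log-TPM profiles with markers and batch effects."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    states = [f"state{i + 1}" for i in range(config.n_states)]
    genes = [f"G{i:05d}" for i in range(config.n_genes)]

    n_marker_total = config.markers_per_state * config.n_states
    base = rng.uniform(*_NONMARKER_BASELINE, size=config.n_genes)
    base[:n_marker_total] = rng.uniform(*_MARKER_BASELINE, size=n_marker_total)

    state_means = np.tile(base[:, None], (1, config.n_states))
    marker_genes: dict[str, list[str]] = {}
    elevation = np.log2(1.0 + config.marker_effect)
    for s, state in enumerate(states):
        rows = slice(s * config.markers_per_state, (s + 1) * config.markers_per_state)
        state_means[rows, s] += elevation
        marker_genes[state] = genes[rows]
    # the detection limit applies to the generating means as well, so the
    # stored ground truth is exactly what cells express on average
    state_means[state_means < _DETECTION_FLOOR] = 0.0

    n_cells = config.n_cells_per_state * config.n_states
    cell_ids = [f"C{i:05d}" for i in range(n_cells)]
    cell_state = np.repeat(np.arange(config.n_states), config.n_cells_per_state)
    patient = rng.integers(0, config.n_patients, size=n_cells)
    batch = rng.normal(0.0, config.batch_sd, size=(config.n_patients, config.n_genes))

    expr = (
        state_means[:, cell_state]
        + batch[patient].T
        + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_cells))
    )
    expr[expr < _DETECTION_FLOOR] = 0.0
    if config.dropout_rate > 0:
        expr[rng.random(expr.shape) < config.dropout_rate] = 0.0

    matrix = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=cell_ids), space="logTPM")
    truth = GroundTruth(
        state_of_cell=pd.Series([states[s] for s in cell_state], index=cell_ids, name="state"),
        state_means=pd.DataFrame(state_means, index=genes, columns=states),
        marker_genes=marker_genes,
        patient_of_cell=pd.Series(patient, index=cell_ids, name="patient"),
    )
    return matrix, truth


def simulate_bulk(
    truth: GroundTruth,
    n_samples: int,
    noise_sd: float,
    seed: int,
    proportions: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Bulk samples as known mixtures of the state mean TPM profiles.

    If ``proportions`` (n_samples x n_states) is omitted, rows are drawn from a
    flat Dirichlet.  Mixing happens in linear TPM space; the returned matrix is
    log2(TPM+1) with additive Gaussian noise of ``noise_sd``.
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    rng = np.random.default_rng(seed)
    states = list(truth.state_means.columns)
    if proportions is None:
        proportions = rng.dirichlet(np.ones(len(states)), size=n_samples)
    proportions = np.asarray(proportions, dtype=float)
    if proportions.shape != (n_samples, len(states)):
        raise ValueError(
            f"proportions must have shape ({n_samples}, {len(states)}), got {proportions.shape}"
        )
    if not np.allclose(proportions.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("proportion rows must sum to 1")

    tpm_means = np.exp2(truth.state_means.to_numpy()) - 1.0  # gene x state
    bulk_tpm = tpm_means @ proportions.T  # gene x sample
    bulk_log = np.log2(bulk_tpm + 1.0)
    if noise_sd > 0:
        bulk_log = np.clip(bulk_log + rng.normal(0.0, noise_sd, size=bulk_log.shape), 0.0, None)

    sample_ids = [f"B{i:04d}" for i in range(n_samples)]
    matrix = ExpressionMatrix(
        pd.DataFrame(bulk_log, index=truth.state_means.index, columns=sample_ids),
        space="logTPM",
    )
    prop_df = pd.DataFrame(proportions, index=sample_ids, columns=states)
    truth.proportions = prop_df
    return matrix, prop_df


def simulate_drug_signatures(
    n_classes: int,
    drugs_per_class: int,
    genes_per_signature: int,
    universe: list[str],
    flip_rate: float,
    seed: int,
    truth: GroundTruth | None = None,
) -> DrugSignatureSet:
    """Drug up/down signatures organized into mechanism classes.

    Each class has a prototype signed vector over the universe (half up, half
    down).  Each drug resamples every position to a different symbol with
    probability ``flip_rate``, perturbing both signs and memberships.
    """
    if not universe:
        raise ValueError("gene universe must be non-empty")
    if genes_per_signature > len(universe):
        raise ValueError("genes_per_signature exceeds universe size")
    if n_classes < 1 or drugs_per_class < 1:
        raise ValueError("n_classes and drugs_per_class must be >= 1")
    if not 0 <= flip_rate <= 1:
        raise ValueError(f"flip_rate must be in [0, 1], got {flip_rate}")

    rng = np.random.default_rng(seed)
    universe = list(universe)
    n_genes = len(universe)
    up: dict[str, list[str]] = {}
    down: dict[str, list[str]] = {}
    moa: dict[str, str] = {}
    for c in range(n_classes):
        label = f"class{c + 1}"
        chosen = rng.choice(n_genes, size=genes_per_signature, replace=False)
        proto = np.zeros(n_genes, dtype=np.int8)
        half = genes_per_signature // 2
        proto[chosen[:half]] = 1
        proto[chosen[half:]] = -1
        for d in range(drugs_per_class):
            drug = f"{label}_drug{d + 1}"
            vec = proto.copy()
            flips = np.flatnonzero(rng.random(n_genes) < flip_rate)
            if flips.size:
                # move each flipped position to one of the two other symbols
                shift = rng.integers(1, 3, size=flips.size)
                vec[flips] = ((vec[flips] + 1 + shift) % 3) - 1
            up[drug] = [universe[i] for i in np.flatnonzero(vec == 1)]
            down[drug] = [universe[i] for i in np.flatnonzero(vec == -1)]
            moa[drug] = label
    sigs = DrugSignatureSet(up=up, down=down, universe=universe, moa=moa)
    if truth is not None:
        truth.drug_class_of = dict(moa)
    return sigs
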