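"""Readers and writers for the plain-text formats used across the pipeline.

All formats are line-oriented text: tab-delimited matrices (genes as rows),
sparse triplet files, GMT gene sets, RNK ranked lists and JSON metadata.
Every writer produces files its paired reader accepts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .matrix import ExpressionMatrix
from .pair_encoding import PairList
from .syndata import GroundTruth

logger = logging.getLogger("statedecon")


def read_expression(
    path: str | Path,
    orientation: str = "genes_rows",
    value_space: str = "logTPM",
) -> ExpressionMatrix:
    """Load a tab-delimited expression matrix.

    ``orientation`` is ``"genes_rows"`` (canonical) or ``"observations_rows"``
    (transposed on load).  Duplicate gene rows are collapsed by mean with a
    warning; duplicate observation IDs and non-numeric cells are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        if orientation == "genes_rows":
            raise ValueError(f"duplicate observation identifiers: {dupes[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if orientation == "observations_rows":
        df = df.T
    elif orientation != "genes_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index.name = None
    df.columns.name = None
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(f"non-numeric value at gene {row!r}, observation {col!r}")
    df = df.astype(float)
    if not df.columns.is_unique:
        dupes = df.columns[df.columns.duplicated()].unique()
        raise ValueError(f"duplicate observation identifiers: {list(dupes[:5])}")
    if not df.index.is_unique:
        dupes = df.index[df.index.duplicated()].unique()
        logger.warning("collapsing %d duplicate gene rows by mean: %s",
                       len(dupes), list(dupes[:5]))
        df = df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(df, space=value_space)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_expression_triplets(path: str | Path, value_space: str = "logTPM") -> ExpressionMatrix:
    """Load a sparse triplet file with header ``gene<TAB>observation<TAB>value``.

    Unlisted (gene, observation) combinations are zero.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "observation": str})
    expected = {"gene", "observation", "value"}
    if set(df.columns) != expected:
        raise ValueError(f"triplet file must have columns {sorted(expected)}, got {list(df.columns)}")
    if df.duplicated(["gene", "observation"]).any():
        dup = df[df.duplicated(["gene", "observation"])].iloc[0]
        raise ValueError(f"duplicate triplet entry for gene {dup['gene']!r}, "
                         f"observation {dup['observation']!r}")
    dense = df.pivot(index="gene", columns="observation", values="value").fillna(0.0)
    dense.index.name = None
    dense.columns.name = None
    return ExpressionMatrix(dense, space=value_space)


def write_expression_triplets(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    long = matrix.values.stack()
    long = long[long != 0]
    out = long.reset_index()
    out.columns = ["gene", "observation", "value"]
    out.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path, column: str = "state") -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if column not in df.columns:
        raise ValueError(f"label file missing column {column!r}")
    return df[column]


def write_labels(labels: pd.Series, path: str | Path, column: str = "state") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels.rename(column).to_csv(path, sep="\t", index_label="observation")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line[:50]!r}")
        name = fields[0]
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        sets[name] = set(g for g in fields[2:] if g)
    return GeneSetCollection(sets)


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "statedecon") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_rnk(ranked: pd.DataFrame, path: str | Path) -> None:
    """Two-column RNK export of a ranked gene table with ``gene`` and ``rho`` columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ranked[["gene", "rho"]].to_csv(path, sep="\t", index=False, header=False)


def read_rts(path: str | Path) -> pd.Series:
    """Two-column tab-delimited repressive-tendency scores (gene, score)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "rts"], dtype={0: str})
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene in repressive-tendency score file")
    return pd.Series(df["rts"].to_numpy(dtype=float), index=df["gene"], name="rts")


def write_pairs(pairs: PairList, concordance: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("gene_a\tgene_b\tconcordance\n")
        for (a, b), c in zip(pairs, concordance):
            fh.write(f"{a}\t{b}\t{c:.17g}\n")


def read_pairs(path: str | Path) -> tuple[PairList, np.ndarray]:
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_a": str, "gene_b": str}, float_precision="round_trip"
    )
    if df.empty:
        return PairList((), np.empty((0, 2), dtype=np.int64)), np.empty(0)
    genes: list[str] = []
    pos: dict[str, int] = {}
    for g in pd.concat([df["gene_a"], df["gene_b"]]):
        if g not in pos:
            pos[g] = len(genes)
            genes.append(g)
    idx = np.array([[pos[a], pos[b]] for a, b in zip(df["gene_a"], df["gene_b"])],
                   dtype=np.int64)
    # canonical order requires first index < second; remap if needed
    if len(idx) and np.any(idx[:, 0] >= idx[:, 1]):
        raise ValueError("pair file is not in canonical order")
    return PairList(tuple(genes), idx), df["concordance"].to_numpy(dtype=float)


def write_drug_signatures(signatures, path: str | Path) -> None:
    """JSON serialization of a drug signature set (up/down lists per drug)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "universe": list(signatures.universe),
        "drugs": {
            drug: {
                "up": list(signatures.up[drug]),
                "down": list(signatures.down[drug]),
                "moa": signatures.moa.get(drug),
                "targets": signatures.targets.get(drug, []),
            }
            for drug in signatures.drugs
        },
    }
    path.write_text(json.dumps(payload, indent=1))


def read_drug_signatures(path: str | Path):
    from .drugs import DrugSignatureSet

    payload = json.loads(Path(path).read_text())
    drugs = payload["drugs"]
    return DrugSignatureSet(
        up={d: list(v["up"]) for d, v in drugs.items()},
        down={d: list(v["down"]) for d, v in drugs.items()},
        universe=list(payload["universe"]),
        moa={d: v["moa"] for d, v in drugs.items() if v.get("moa")},
        targets={d: list(v["targets"]) for d, v in drugs.items() if v.get("targets")},
    )


def signatures_to_gmt(signatures, path: str | Path) -> None:
    """GMT pairs export: one ``<drug>_UP`` and one ``<drug>_DOWN`` set per drug."""
    sets: dict[str, list[str]] = {}
    for drug in signatures.drugs:
        if signatures.up[drug]:
            sets[f"{drug}_UP"] = list(signatures.up[drug])
        if signatures.down[drug]:
            sets[f"{drug}_DOWN"] = list(signatures.down[drug])
    write_gmt(sets, path)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "state_of_cell": truth.state_of_cell.to_dict(),
        "state_means": {
            "genes": list(truth.state_means.index),
            "states": list(truth.state_means.columns),
            "values": truth.state_means.to_numpy().tolist(),
        },
        "marker_genes": truth.marker_genes,
        "proportions": None
        if truth.proportions is None
        else {
            "samples": list(truth.proportions.index),
            "states": list(truth.proportions.columns),
            "values": truth.proportions.to_numpy().tolist(),
        },
        "drug_class_of": truth.drug_class_of,
    }
    path.write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    sm = payload["state_means"]
    props = payload.get("proportions")
    return GroundTruth(
        state_of_cell=pd.Series(payload["state_of_cell"], name="state"),
        state_means=pd.DataFrame(sm["values"], index=sm["genes"], columns=sm["states"]),
        marker_genes={k: list(v) for k, v in payload["marker_genes"].items()},
        proportions=None
        if props is None
        else pd.DataFrame(props["values"], index=props["samples"], columns=props["states"]),
        drug_class_of=payload.get("drug_class_of", {}),
    )
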