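"""Plain-text readers and writers for the pipeline's tabular artifacts.

Everything is TSV (matrices, edge lists, tables) or JSON (catalogs,
annotations, ground truth) so that runs are diffable and portable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GroundTruth
from .datatypes import (
    DensityMatrix,
    ExpressionMatrix,
    FeatureMatrix,
    FunctionalConnectome,
    StructuralConnectome,
    TimeSeriesStack,
)


def write_density(density: DensityMatrix, path: str | Path) -> None:
    path = Path(path)
    density.values.to_csv(path, sep="\t")
    density.subtype_meta.drop(columns=["func"], errors="ignore").to_csv(
        path.with_suffix(".meta.tsv"), sep="\t"
    )
    if density.region_ontology is not None:
        density.region_ontology.to_csv(path.with_suffix(".ontology.tsv"), sep="\t")


def read_density(path: str | Path) -> DensityMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(path.with_suffix(".meta.tsv"), sep="\t", index_col=0)
    ont_path = path.with_suffix(".ontology.tsv")
    ontology = None
    if ont_path.exists():
        ontology = pd.read_csv(ont_path, sep="\t", index_col=0).iloc[:, 0]
    return DensityMatrix(values=values, subtype_meta=meta, region_ontology=ontology)


def write_timeseries(stack: TimeSeriesStack, out_dir: str | Path) -> None:
    """One regions x T TSV per subject, plus motion traces and metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, sid in enumerate(stack.subject_ids):
        pd.DataFrame(stack.values[i], index=stack.region_ids).to_csv(
            out / f"{sid}.tsv", sep="\t"
        )
    meta = {"subject_ids": list(stack.subject_ids), "state": list(stack.state)}
    (out / "stack.json").write_text(json.dumps(meta, indent=1))
    if stack.motion is not None:
        pd.DataFrame(stack.motion, index=stack.subject_ids).to_csv(
            out / "motion.tsv", sep="\t"
        )


def read_timeseries(out_dir: str | Path) -> TimeSeriesStack:
    out = Path(out_dir)
    meta = json.loads((out / "stack.json").read_text())
    frames = [
        pd.read_csv(out / f"{sid}.tsv", sep="\t", index_col=0)
        for sid in meta["subject_ids"]
    ]
    motion = None
    if (out / "motion.tsv").exists():
        motion = pd.read_csv(out / "motion.tsv", sep="\t", index_col=0).values
    return TimeSeriesStack(
        values=np.stack([f.values for f in frames]),
        region_ids=list(frames[0].index),
        subject_ids=meta["subject_ids"],
        state=meta["state"],
        motion=motion,
    )


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.values.to_csv(path, sep="\t")
    sidecar = {
        "normalized": matrix.normalized,
        "catalog": {
            f: {"family": matrix.catalog.loc[f, "family"]} for f in matrix.catalog.index
        },
    }
    path.with_suffix(".catalog.json").write_text(json.dumps(sidecar, indent=1))


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col=0)
    sidecar = json.loads(path.with_suffix(".catalog.json").read_text())
    catalog = pd.DataFrame.from_dict(sidecar["catalog"], orient="index")
    catalog.index.name = "feature"
    return FeatureMatrix(
        values=values, catalog=catalog, normalized=sidecar["normalized"]
    )


def write_edge_list(sc: StructuralConnectome, path: str | Path) -> None:
    rows = []
    n = len(sc.region_ids)
    for i in range(n):
        for j in range(n):
            if sc.weights[i, j] != 0:
                rows.append(
                    (sc.region_ids[i], sc.region_ids[j], sc.weights[i, j], sc.pvalues[i, j])
                )
    pd.DataFrame(rows, columns=["source", "target", "weight", "p"]).to_csv(
        path, sep="\t", index=False
    )


def write_fc_matrix(fc: FunctionalConnectome, path: str | Path) -> None:
    pd.DataFrame(fc.values, index=fc.region_ids, columns=fc.region_ids).to_csv(
        path, sep="\t"
    )


def read_fc_matrix(path: str | Path, state: str = "awake") -> FunctionalConnectome:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FunctionalConnectome(values=df.values, region_ids=list(df.index), state=state)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(matrix.values).to_csv(path, sep="\t")


def write_annotation(annotation: dict[str, list[str]], path: str | Path) -> None:
    Path(path).write_text(json.dumps(annotation, indent=1))


def read_annotation(path: str | Path) -> dict[str, list[str]]:
    return json.loads(Path(path).read_text())


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "planted_cluster_of_subtype": truth.planted_cluster_of_subtype.to_dict(),
        "planted_maps": truth.planted_maps.to_dict(),
        "lifetimes": {
            k: (None if not np.isfinite(v) else v) for k, v in truth.lifetimes.items()
        },
        "true_effects": truth.true_effects,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
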