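"""Readers and writers for the pipeline's text interchange formats.

Datasets travel as delimited text (columns ``id``, optional ``smiles``,
optional ``fp`` bitstring, ``label``); feature/embedding matrices as
delimited text with a one-line ``#`` header recording the sample ids; APD
points and analysis results as JSON / JSON-lines.  Every result document
embeds the fully resolved run configuration so a run can be reproduced
from its output alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_features import Fingerprint, MoleculeRecord, MolecularDataset
from .model_bench import APDPoint
from .repr_align import FeatureMatrix

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_matrix",
    "write_matrix",
    "read_apd_points",
    "write_apd_points",
    "write_json_result",
]


def read_dataset(path: str | Path, dataset_id: str | None = None) -> MolecularDataset:
    """Read a molecular dataset from delimited text.

    Requires ``id`` and ``label`` columns; ``smiles`` and ``fp`` (a '0'/'1'
    bitstring) are optional.  Errors name the offending row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if df.empty:
        raise ValueError(f"{path}: no records")
    missing = {"id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    seen = set()
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        rid = str(row["id"])
        if rid in seen:
            raise ValueError(f"{path} line {line}: duplicate id {rid!r}")
        seen.add(rid)
        raw = str(row["label"]).strip()
        if raw not in {"0", "1"}:
            raise ValueError(f"{path} line {line}: non-binary label {raw!r}")
        smiles = None
        if "smiles" in df.columns and pd.notna(row["smiles"]):
            smiles = str(row["smiles"])
        fp = None
        if "fp" in df.columns and pd.notna(row["fp"]):
            try:
                fp = Fingerprint.from_bitstring(str(row["fp"]))
            except ValueError as e:
                raise ValueError(f"{path} line {line}: {e}") from None
        records.append(MoleculeRecord(id=rid, label=int(raw), smiles=smiles, fingerprint=fp))
    return MolecularDataset(records=tuple(records), dataset_id=dataset_id or path.stem)


def write_dataset(dataset: MolecularDataset, path: str | Path) -> None:
    rows = []
    for r in dataset.records:
        rows.append({
            "id": r.id,
            "smiles": r.smiles if r.smiles is not None else "",
            "fp": r.fingerprint.to_bitstring() if r.fingerprint is not None else "",
            "label": r.label,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_matrix(matrix: FeatureMatrix | np.ndarray, path: str | Path,
                 sample_ids: Sequence | None = None) -> None:
    """Delimited matrix with a '#' header line carrying the sample ids."""
    if isinstance(matrix, FeatureMatrix):
        values, ids = matrix.values, matrix.sample_ids
    else:
        values = np.asarray(matrix, dtype=float)
        ids = tuple(sample_ids) if sample_ids is not None else tuple(range(values.shape[0]))
    with open(path, "w") as fh:
        fh.write("# sample_ids\t" + "\t".join(str(i) for i in ids) + "\n")
        np.savetxt(fh, values, delimiter="\t")


def read_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# sample_ids\t"):
            raise ValueError(f"{path}: missing sample-id header line")
        ids = tuple(header.rstrip("\n").split("\t")[1:])
        values = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if values.shape[0] != len(ids):
        raise ValueError(f"{path}: {len(ids)} sample ids for {values.shape[0]} rows")
    return FeatureMatrix(values=values, sample_ids=ids, centered=False)


def write_apd_points(points: Sequence[APDPoint], path: str | Path) -> None:
    """APD points as JSON-lines."""
    with open(path, "w") as fh:
        for p in points:
            fh.write(json.dumps({
                "dataset_id": p.dataset_id,
                "tagA": p.pair[0], "tagB": p.pair[1],
                "alignment": p.alignment, "perf_diff": p.perf_diff,
                "mcc_a": p.mcc_a, "mcc_b": p.mcc_b,
            }) + "\n")


def read_apd_points(path: str | Path) -> list[APDPoint]:
    points = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                points.append(APDPoint(
                    dataset_id=rec["dataset_id"],
                    pair=(rec.get("tagA", "A"), rec.get("tagB", "B")),
                    alignment=rec["alignment"],
                    perf_diff=rec["perf_diff"],
                    mcc_a=rec.get("mcc_a", rec["perf_diff"] / 2),
                    mcc_b=rec.get("mcc_b", -rec["perf_diff"] / 2),
                ))
            except (KeyError, json.JSONDecodeError) as e:
                raise ValueError(f"{path} line {lineno}: {e}") from None
    if not points:
        raise ValueError(f"{path}: no APD points")
    return points


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        return super().default(obj)


def write_json_result(result: dict, path: str | Path, config: dict | None = None) -> None:
    """Write a result document, embedding the resolved run configuration."""
    doc = dict(result)
    if config is not None:
        doc["config"] = config
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")
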