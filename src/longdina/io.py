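"""Plain-text interchange: CSV for matrices, JSON for parameters and reports.

All on-disk indices (items, occasions, attributes, persons) are 1-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import AccuracyReport
from .model import ItemParameters, QMatrixSet, ResponseData, StructuralParameters

__all__ = [
    "write_responses_csv", "read_responses_csv",
    "write_qmatrix_csv", "read_qmatrix_csv",
    "write_parameters_json", "read_parameters_json",
    "write_report_json", "read_report_json",
]


def write_responses_csv(responses: ResponseData, path) -> None:
    """Long-format responses: columns person, item, occasion, y."""
    N, I, T = responses.y.shape
    person, item, occ = np.meshgrid(np.arange(1, N + 1), np.arange(1, I + 1), np.arange(1, T + 1), indexing="ij")
    pd.DataFrame({
        "person": person.ravel(), "item": item.ravel(), "occasion": occ.ravel(),
        "y": responses.y.ravel(),
    }).to_csv(path, index=False)


def read_responses_csv(path) -> ResponseData:
    df = pd.read_csv(path)
    N, I, T = (int(df[c].max()) for c in ("person", "item", "occasion"))
    y = np.zeros((N, I, T), dtype=np.int8)
    y[df["person"] - 1, df["item"] - 1, df["occasion"] - 1] = df["y"]
    return ResponseData(y)


def write_qmatrix_csv(qmat: QMatrixSet, path) -> None:
    """Long-format Q-matrix: occasion, item, attribute_1..attribute_K."""
    I, K, T = qmat.entries.shape
    rows = []
    for t in range(T):
        for i in range(I):
            rows.append({"occasion": t + 1, "item": i + 1,
                         **{f"attribute_{k + 1}": int(qmat.entries[i, k, t]) for k in range(K)}})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_qmatrix_csv(path, anchor_items=()) -> QMatrixSet:
    df = pd.read_csv(path)
    attr_cols = sorted((c for c in df.columns if c.startswith("attribute_")), key=lambda c: int(c.split("_")[1]))
    I, T, K = int(df["item"].max()), int(df["occasion"].max()), len(attr_cols)
    q = np.zeros((I, K, T), dtype=np.int8)
    q[df["item"] - 1, :, df["occasion"] - 1] = df[attr_cols].to_numpy(dtype=np.int8)
    return QMatrixSet(q, anchor_items=tuple(anchor_items))


def write_parameters_json(items: ItemParameters, struct: StructuralParameters, path,
                          anchor_items=None) -> None:
    """Parameter set as JSON; lambda arrays are stored occasion-major (T x I)."""
    anchors = items.anchor_items if anchor_items is None else tuple(anchor_items)
    payload = {
        "lambda0": items.lambda0.T.tolist(),
        "lambda1": items.lambda1.T.tolist(),
        "beta": struct.beta.tolist(),
        "delta": struct.delta.tolist(),
        "mu": struct.mu.tolist(),
        "sigma": struct.sigma_mat.tolist(),
        "anchor_items": list(anchors),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_parameters_json(path) -> tuple[ItemParameters, StructuralParameters]:
    d = json.loads(Path(path).read_text())
    anchors = tuple(d.get("anchor_items", ()))
    items = ItemParameters(np.asarray(d["lambda0"]).T, np.asarray(d["lambda1"]).T, anchor_items=anchors)
    struct = StructuralParameters(d["beta"], d["delta"], d["mu"], d["sigma"])
    return items, struct


def write_report_json(report: AccuracyReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))


def read_report_json(path) -> AccuracyReport:
    return AccuracyReport.from_dict(json.loads(Path(path).read_text()))
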