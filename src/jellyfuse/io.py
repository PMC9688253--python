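"""Reading and writing the feature-table, weight and trace formats.

The delimited-text layout is one sample per row with columns named
``block:<extractor_id>:<index>`` plus a trailing ``label`` column; the HDF5
layout stores one dataset per block plus a ``labels`` vector.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fusion import FeatureBlock, FusedFeatureSet, MultiViewDataset, SelectionMask, WeightScheme

__all__ = [
    "write_feature_csv",
    "read_feature_csv",
    "write_feature_hdf5",
    "read_feature_hdf5",
    "dataset_to_frame",
    "frame_to_dataset",
    "export_weights_csv",
    "export_trace_csv",
]


def dataset_to_frame(dataset: MultiViewDataset) -> pd.DataFrame:
    cols = {}
    for block in dataset.blocks:
        for j in range(block.d):
            cols[f"block:{block.extractor_id}:{j}"] = block.matrix[:, j]
    cols["label"] = dataset.labels
    return pd.DataFrame(cols)


def frame_to_dataset(df: pd.DataFrame, label_col: str = "label") -> MultiViewDataset:
    """Rebuild a multi-view dataset from a ``block:<id>:<index>`` frame.

    Block order follows first appearance in the columns; indices within a
    block are sorted numerically.
    """
    if label_col not in df.columns:
        raise ValueError(f"missing label column {label_col!r}")
    groups: dict[str, list[tuple[int, str]]] = {}
    for col in df.columns:
        if col == label_col:
            continue
        parts = str(col).split(":")
        if len(parts) != 3 or parts[0] != "block":
            raise ValueError(f"unrecognized feature column {col!r}")
        groups.setdefault(parts[1], []).append((int(parts[2]), col))
    if not groups:
        raise ValueError("no block:<id>:<index> feature columns found")
    blocks = []
    for ext_id, cols in groups.items():
        cols.sort()
        blocks.append(FeatureBlock(ext_id, df[[c for _, c in cols]].to_numpy(dtype=float)))
    return MultiViewDataset(blocks, df[label_col].to_numpy(dtype=int))


def write_feature_csv(dataset: MultiViewDataset, path) -> None:
    dataset_to_frame(dataset).to_csv(path, index=False)


def read_feature_csv(path, label_col: str = "label") -> MultiViewDataset:
    return frame_to_dataset(pd.read_csv(path), label_col=label_col)


def write_feature_hdf5(dataset: MultiViewDataset, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        grp = f.create_group("blocks")
        for i, block in enumerate(dataset.blocks):
            ds = grp.create_dataset(f"{i:03d}", data=block.matrix)
            ds.attrs["extractor_id"] = block.extractor_id
        f.create_dataset("labels", data=dataset.labels)


def read_feature_hdf5(path) -> MultiViewDataset:
    import h5py

    with h5py.File(path, "r") as f:
        blocks = [
            FeatureBlock(f["blocks"][key].attrs["extractor_id"], f["blocks"][key][()])
            for key in sorted(f["blocks"])
        ]
        labels = f["labels"][()]
    return MultiViewDataset(blocks, labels)


def export_weights_csv(
    fused: FusedFeatureSet | None,
    weights: WeightScheme,
    path,
    provenance: pd.DataFrame | None = None,
    mask: SelectionMask | None = None,
) -> pd.DataFrame:
    """Write a weight vector (and optional keep flags) as CSV rows of
    (index, extractor_id, weight, selected)."""
    n = len(weights.weights)
    if provenance is None and fused is not None:
        provenance = fused.column_provenance
    ext = (
        provenance["extractor_id"].to_numpy()
        if provenance is not None and len(provenance) == n
        else np.array(["" for _ in range(n)])
    )
    selected = mask.keep if mask is not None else np.ones(n, dtype=bool)
    df = pd.DataFrame(
        {
            "index": np.arange(n),
            "extractor_id": ext,
            "weight": weights.weights,
            "selected": selected,
        }
    )
    df.to_csv(path, index=False)
    return df


def export_trace_csv(result, path) -> None:
    result.trace_frame().to_csv(path, index=False)


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
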