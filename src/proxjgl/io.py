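"""Readers and writers for on-disk artifacts.

Everything is delimited text (CSV by default, TSV via ``sep``): datasets are
either one file per class or one long table with a class-label column;
precision sets are one square matrix file per class plus a JSON manifest;
edge lists, solver traces, CV tables and metrics are plain tables parseable
by any delimited-text reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import MultiClassDataset, PrecisionSet

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_precision_set",
    "write_precision_set",
    "write_edge_list",
    "write_trace",
]

_FLOAT_FMT = "%.17g"  # round-trip exact for doubles


def _read_table(path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    bad = df.columns[df.isna().any(axis=0)]
    if len(bad):
        col = bad[0]
        row = int(df[df[col].isna()].index[0])
        raise ValueError(f"missing value in {path} at row {row + 2}, column {col!r}")
    return df


def read_dataset(
    paths,
    class_column: str | None = None,
    sep: str = ",",
) -> MultiClassDataset:
    """Load a multi-class dataset.

    ``paths`` is either a list of per-class files (rows = observations,
    header row = feature names) or a single long table whose ``class_column``
    labels the class of each row.  Non-numeric payload cells raise with the
    offending row/column named.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if class_column is not None:
        if len(paths) != 1:
            raise ValueError("class_column applies to a single long table")
        df = _read_table(paths[0], sep)
        if class_column not in df.columns:
            raise ValueError(f"class column {class_column!r} not found in {paths[0]}")
        labels = sorted(df[class_column].unique(), key=str)
        feats = [c for c in df.columns if c != class_column]
        mats, names = [], feats
        for lab in labels:
            sub = df.loc[df[class_column] == lab, feats]
            mats.append(_numeric_payload(sub, paths[0]))
        ds = MultiClassDataset(mats, class_labels=list(labels))
    else:
        mats, labels, names = [], [], None
        for path in paths:
            df = _read_table(path, sep)
            if names is None:
                names = list(df.columns)
            elif list(df.columns) != names:
                raise ValueError(f"feature names in {path} differ from {paths[0]}")
            mats.append(_numeric_payload(df, path))
            labels.append(Path(path).stem)
        ds = MultiClassDataset(mats, class_labels=labels)
    ds.feature_names = list(names)
    return ds


def _numeric_payload(df: pd.DataFrame, path) -> np.ndarray:
    try:
        return df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                row = int(coerced[coerced.isna()].index[0])
                raise ValueError(
                    f"non-numeric cell in {path} at row {row + 2}, column {col!r}"
                )
        raise


def write_dataset(
    dataset: MultiClassDataset,
    path,
    class_column: str = "class",
    sep: str = ",",
) -> None:
    """Write a dataset as one long table with a class-label column."""
    names = getattr(dataset, "feature_names", None) or [
        f"x{i + 1}" for i in range(dataset.p)
    ]
    frames = []
    for lab, x in zip(dataset.class_labels, dataset.samples_per_class):
        df = pd.DataFrame(x, columns=names)
        df.insert(0, class_column, lab)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep=sep, index=False, float_format=_FLOAT_FMT
    )


def write_precision_set(
    theta: PrecisionSet,
    out_dir,
    feature_names: list | None = None,
    class_labels: list | None = None,
    prefix: str = "theta",
    sep: str = ",",
) -> list:
    """One square matrix file per class (feature names as header and index
    column) plus a ``<prefix>_manifest.json``; full float precision."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = feature_names or [f"x{i + 1}" for i in range(theta.p)]
    labels = class_labels or list(range(1, theta.K + 1))
    files = []
    for k, lab in enumerate(labels):
        df = pd.DataFrame(theta.matrices[k], index=names, columns=names)
        path = out_dir / f"{prefix}_class_{lab}.csv"
        df.to_csv(path, sep=sep, float_format=_FLOAT_FMT, index_label="feature")
        files.append(path)
    manifest = {
        "K": theta.K,
        "p": theta.p,
        "class_labels": [str(lab) for lab in labels],
        "files": [f.name for f in files],
        "feature_names": list(names),
    }
    with open(out_dir / f"{prefix}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return files


def read_precision_set(out_dir, prefix: str = "theta", sep: str = ","):
    """Round-trip reader for :func:`write_precision_set`.

    Returns ``(PrecisionSet, feature_names, class_labels)``.
    """
    out_dir = Path(out_dir)
    with open(out_dir / f"{prefix}_manifest.json") as fh:
        manifest = json.load(fh)
    mats = []
    for name in manifest["files"]:
        df = pd.read_csv(out_dir / name, sep=sep, index_col=0,
                         float_precision="round_trip")
        mats.append(df.to_numpy(dtype=float))
    return (
        PrecisionSet(np.stack(mats)),
        manifest["feature_names"],
        manifest["class_labels"],
    )


def write_edge_list(
    theta: PrecisionSet,
    path=None,
    zero_tol: float = 1e-6,
    feature_names: list | None = None,
    class_labels: list | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Selected edges (i<j, |theta| > zero_tol) as rows
    (class, feature_i, feature_j, value, shared) — ``shared`` marks edges
    present in every class, distinguishing the common structure from
    class-specific ones."""
    names = feature_names or [f"x{i + 1}" for i in range(theta.p)]
    labels = class_labels or list(range(1, theta.K + 1))
    iu = np.triu_indices(theta.p, k=1)
    selected = [
        set(zip(*[idx[np.abs(theta.matrices[k][iu]) > zero_tol] for idx in iu]))
        for k in range(theta.K)
    ]
    common = set.intersection(*selected) if selected else set()
    rows = []
    for k, lab in enumerate(labels):
        for i, j in sorted(selected[k]):
            rows.append(
                {
                    "class": lab,
                    "feature_i": names[i],
                    "feature_j": names[j],
                    "value": theta.matrices[k][i, j],
                    "shared": (i, j) in common,
                }
            )
    df = pd.DataFrame(
        rows, columns=["class", "feature_i", "feature_j", "value", "shared"]
    )
    if path is not None:
        df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
    return df


def write_trace(trace, path, sep: str = ",") -> None:
    """Solver trace as a delimited table, one row per iteration."""
    trace.to_frame().to_csv(path, sep=sep, index=False)
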