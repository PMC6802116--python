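"""Readers and writers for expression/count matrices and gene sets.

TSV is the native format: first column holds feature identifiers, the
header row holds sample identifiers.  GCT 1.2 is supported read-only.
MTX input is a Matrix Market triplet file with two sidecar identifier
files (``<stem>.rows.txt`` and ``<stem>.cols.txt``, one id per line).
Gene sets use the GMT dialect (name, description, members per line).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import ExpressionMatrix, ValidationError

__all__ = ["read_matrix", "write_matrix", "read_gmt", "write_gmt"]


def read_matrix(path: str, format: str | None = None) -> ExpressionMatrix:
    """Read a non-negative features × samples matrix.

    Parameters
    ----------
    path
        Input file.  For MTX, sidecar files ``<stem>.rows.txt`` and
        ``<stem>.cols.txt`` must sit next to it.
    format
        ``tsv``, ``gct`` or ``mtx``; inferred from the extension when
        omitted.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = {"txt": "tsv", "tab": "tsv"}.get(ext, ext)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return _from_frame(df)
    if format == "gct":
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        # GCT 1.2 carries a Description column after the id column
        if df.columns[0].lower() == "description":
            df = df.drop(columns=df.columns[0])
        return _from_frame(df)
    if format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        stem = path[: -len(".mtx")] if path.endswith(".mtx") else path
        rows = _read_ids(stem + ".rows.txt")
        cols = _read_ids(stem + ".cols.txt")
        return ExpressionMatrix(np.asarray(mat, dtype=float), rows, cols)
    raise ValidationError(f"unknown matrix format {format!r}")


def _read_ids(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _from_frame(df: pd.DataFrame) -> ExpressionMatrix:
    return ExpressionMatrix(
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def write_matrix(mat: ExpressionMatrix, path: str, format: str = "tsv") -> None:
    """Write a matrix as TSV (feature ids first column) or MTX triplet."""
    if format == "tsv":
        df = pd.DataFrame(mat.values, index=mat.feature_ids, columns=mat.sample_ids)
        df.to_csv(path, sep="\t")
    elif format == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(mat.values))
        stem = path[: -len(".mtx")] if path.endswith(".mtx") else path
        for suffix, ids in ((".rows.txt", mat.feature_ids), (".cols.txt", mat.sample_ids)):
            with open(stem + suffix, "w") as fh:
                fh.write("\n".join(ids) + "\n")
    else:
        raise ValidationError(f"unknown matrix format {format!r}")


def read_gmt(path: str) -> dict[str, list[str]]:
    """Read named gene sets from a GMT file."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
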