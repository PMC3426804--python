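"""Tab-delimited readers and writers for matrices, labels and results.

All files are TSV with headers.  Matrices are genes x samples with a
gene-id first column; floats are serialised at 17 significant digits so
a write/read round trip is value-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .simulate import ExpressionExperiment

__all__ = [
    "read_matrix",
    "read_labels",
    "write_table",
    "write_experiment",
]

_FLOAT_FMT = "%.17g"


def _scan_tsv(path: Path) -> int:
    """Validate rectangular shape; return the column count."""
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise ParseError(f"{path}: empty file")
        ncol = len(header.rstrip("\n").split("\t"))
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            nfield = len(line.rstrip("\n").split("\t"))
            if nfield != ncol:
                raise ParseError(
                    f"{path}: line {lineno}: expected {ncol} fields, got {nfield}"
                )
    return ncol


def read_matrix(path) -> pd.DataFrame:
    """Read a genes x samples TSV matrix (gene ids in the first column)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    _scan_tsv(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ParseError(f"{path}: duplicate gene ids: {', '.join(map(str, dup))}")
    return df


def read_labels(path) -> pd.Series:
    """Read a two-column (sample_id, group) TSV into a Series."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    _scan_tsv(path)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected two columns (sample_id, group)")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="group")


def write_table(data, path, index: bool = False, index_label=None) -> None:
    """Write a DataFrame as TSV with 17-significant-digit floats."""
    df = data if isinstance(data, pd.DataFrame) else pd.DataFrame(data)
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format=_FLOAT_FMT)


def write_experiment(exp: ExpressionExperiment, outdir) -> dict:
    """Write matrix.tsv, labels.tsv, truth.tsv (and config.yaml) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_cols = exp.log2_matrix.shape[1]
    width = max(4, len(str(n_cols)))
    sample_ids = [f"s{i + 1:0{width}d}" for i in range(n_cols)]

    matrix = pd.DataFrame(exp.log2_matrix, index=exp.gene_ids, columns=sample_ids)
    paths = {
        "matrix": outdir / "matrix.tsv",
        "labels": outdir / "labels.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
    }
    write_table(matrix, paths["matrix"], index=True, index_label="gene_id")
    write_table(
        pd.DataFrame({"sample_id": sample_ids, "group": exp.group_labels}),
        paths["labels"],
    )
    write_table(exp.truth, paths["truth"])
    exp.config.to_yaml(paths["config"])
    return paths


def load_experiment_arrays(matrix_path, labels_path):
    """Read a matrix + label pair, aligning label order to matrix columns."""
    matrix = read_matrix(matrix_path)
    labels = read_labels(labels_path)
    missing = [c for c in matrix.columns if c not in labels.index]
    if missing:
        raise ParseError(f"labels missing for samples: {', '.join(map(str, missing))}")
    aligned = labels.loc[list(matrix.columns)]
    return matrix.to_numpy(dtype=float), aligned.to_numpy(), np.asarray(matrix.index)
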