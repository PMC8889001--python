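"""Readers, writers and the preprocessing steps used ahead of clustering.

Dense matrices come from CSV/TSV (rows = points; header row and leading id
column are auto-detected).  Sparse single-cell expression matrices come from
MatrixMarket coordinate files plus row/column name files, with an orientation
flag for genes x cells layouts.  Preprocessing: highly-variable-gene (HVG)
selection keeps the top-k columns by variance, and a spatial density filter
drops points lying in sparsely occupied lat/lon grid cells (default: fewer
than 90 locations per 0.01 degree cell).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data import Dataset

log = logging.getLogger("wfclust")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_dense(path) -> Dataset:
    """Read a dense CSV/TSV matrix, one row per point.

    A non-numeric first row is treated as a header; a non-numeric first column
    as point ids.  Both detections are logged.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str)
    if raw.empty:
        raise ValueError(f"{path}: empty file")

    def _numeric(series) -> bool:
        return pd.to_numeric(series, errors="coerce").notna().all()

    # id column first (an all-text first column), then header (text first row)
    has_ids = raw.shape[1] > 1 and not _numeric(raw.iloc[:, 0])
    data = raw.iloc[:, 1:] if has_ids else raw
    if has_ids:
        log.info("read_dense %s: non-numeric first column treated as ids", path.name)
    has_header = not _numeric(data.iloc[0])
    body = data.iloc[1:] if has_header else data
    if has_header:
        log.info("read_dense %s: header row detected and skipped", path.name)
    if body.empty:
        raise ValueError(f"{path}: no data rows")
    values = body.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(np.isnan(values))
    if bad.size:
        r, c = bad[0]
        raise ValueError(f"{path}: non-numeric cell at row {int(r)}, column {int(c)}")
    return Dataset.from_array(values)


def write_dense(path, X: Dataset) -> None:
    path = Path(path)
    np.savetxt(path, X.values, delimiter=_sep_for(path), fmt="%.17g")


def read_mtx(
    matrix_path,
    row_names: Optional[str] = None,
    col_names: Optional[str] = None,
    transpose: bool = False,
) -> Tuple[Dataset, List[str], List[str]]:
    """Read a MatrixMarket expression matrix with cells as points (rows).

    ``transpose`` declares the file is genes x cells and flips it.  Name files
    (one name per line) must match the corresponding axis length.
    """
    m = scipy.io.mmread(str(matrix_path))
    if scipy.sparse.issparse(m):
        m = m.toarray()
    m = np.asarray(m, dtype=float)
    point_name_file, feat_name_file = row_names, col_names
    if transpose:  # file is genes x cells: its column names label the points
        m = m.T
        point_name_file, feat_name_file = col_names, row_names
    rows = _read_names(point_name_file) if point_name_file else [str(i) for i in range(m.shape[0])]
    cols = _read_names(feat_name_file) if feat_name_file else [str(j) for j in range(m.shape[1])]
    if len(rows) != m.shape[0]:
        raise ValueError(f"row-name file has {len(rows)} names for {m.shape[0]} rows")
    if len(cols) != m.shape[1]:
        raise ValueError(f"column-name file has {len(cols)} names for {m.shape[1]} columns")
    return Dataset.from_array(m), rows, cols


def _read_names(path) -> List[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def select_hvg(X: Dataset, k: int, lognorm: bool = False) -> Tuple[Dataset, np.ndarray]:
    """Keep the top-k columns by (population) variance, in original order.

    Ties break toward the smaller column index.  ``lognorm`` applies
    log1p before computing variances (selection only; returned values are
    the original ones).
    """
    if k > X.d:
        raise ValueError(f"k={k} exceeds dimension d={X.d}")
    v = np.log1p(X.values) if lognorm else X.values
    var = v.var(axis=0, ddof=0)
    order = np.argsort(-var, kind="stable")[:k]
    keep = np.sort(order)
    log.info("select_hvg: kept %d/%d columns", k, X.d)
    return Dataset.from_array(X.values[:, keep]), keep


def density_filter(
    X: Dataset, cell_size: float = 0.01, min_count: int = 90
) -> Tuple[Dataset, np.ndarray]:
    """Drop 2-d points lying in grid cells occupied by fewer than min_count points.

    Cells are half-open cell_size x cell_size squares on the absolute
    lat/lon grid (defaults: 0.01 degree cells, 90 locations).
    Returns the filtered dataset and the retained row indices.
    """
    if X.d != 2:
        raise ValueError("density_filter requires 2-d (lon/lat) data")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    keys = np.floor(X.values / cell_size).astype(np.int64)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    keep = np.nonzero(counts[inverse] >= min_count)[0]
    log.info("density_filter: retained %d/%d points", keep.size, X.n)
    if keep.size == 0:
        raise ValueError("density filter removed every point")
    return Dataset.from_array(X.values[keep]), keep


def write_result(result, outdir) -> None:
    """Write per-scale labels (TSV), hierarchy (JSON), schedule, config, log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = result.labels_matrix()
    header = "point_id\t" + "\t".join(f"scale_{s}" for s in range(1, mat.shape[1] + 1))
    with open(outdir / "labels.tsv", "w") as fh:
        fh.write(header + "\n")
        for i in range(mat.shape[0]):
            fh.write(str(i) + "\t" + "\t".join(map(str, mat[i])) + "\n")
    nodes = [
        {"scale": nd.scale, "cluster_id": nd.cluster_id, "size": nd.size, "parent": nd.parent}
        for nd in result.hierarchy.nodes
    ]
    (outdir / "hierarchy.json").write_text(
        json.dumps({"repaired_parents": result.hierarchy.repaired_parents, "nodes": nodes})
    )
    (outdir / "schedule.json").write_text(result.schedule.to_json())
    (outdir / "config.json").write_text(result.config.to_json())
    with open(outdir / "run.log", "w") as fh:
        fh.write(f"coding\t{result.coding}\n")
        for rec in result.log:
            fh.write(
                f"scale={rec['scale']}\tthreshold={rec['threshold']:.6g}\t"
                f"edges={rec['edges']}\tclusters={rec['clusters']}\t"
                f"isolated={rec['isolated']}\n"
            )


def read_labels(path) -> List[str]:
    """Read a ground-truth label file: one label per line (optionally id<TAB>label)."""
    out = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.split("\t")
        out.append(parts[-1])
    return out
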