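"""TSV/CSV/YAML readers and writers for all dcakit artifacts.

TSV is the canonical dialect (tab-separated, ``#`` comment lines, UTF-8);
CSV is accepted on read by delimiter sniffing.  Every writer can prepend
a ``#``-prefixed header recording the resolved configuration and seed, so
outputs are self-describing.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .counts import CellCountTable
from .errors import ValidationError
from .model import DesignMatrix
from .similarity import KnnGraph, SimilarityMatrix

logger = logging.getLogger(__name__)


def _sniff_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "," if line.count(",") > line.count("\t") else "\t"
    raise ValidationError(f"{path}: file has no data lines")


def _read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    try:
        return pd.read_csv(
            path, sep=_sniff_sep(path), comment="#", index_col=index_col
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def _write_table(
    df: pd.DataFrame, path: str | Path, header_comment: str | None = None,
    index: bool = True,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=index)
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_counts(path: str | Path) -> CellCountTable:
    """Read a sample-by-cell-type count TSV (first column = sample id)."""
    df = _read_table(path)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValidationError(f"{path}: non-numeric entries in count table")
    if np.any(arr < 0):
        r, c = np.argwhere(arr < 0)[0]
        raise ValidationError(
            f"{path}: negative count at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if not np.allclose(arr, np.round(arr)):
        raise ValidationError(f"{path}: counts must be integers")
    return CellCountTable.from_frame(df)


def write_counts(
    table: CellCountTable, path: str | Path, header_comment: str | None = None
) -> None:
    _write_table(table.to_frame(), path, header_comment)


def read_design(
    path: str | Path, tested: Sequence[str] | None = None
) -> DesignMatrix:
    """Read a per-sample covariate TSV (first column = sample id)."""
    df = _read_table(path)
    return DesignMatrix.from_frame(df, tested)


def write_design(design: DesignMatrix, path: str | Path,
                 header_comment: str | None = None) -> None:
    df = design.covariates.copy()
    df.index = pd.Index(design.sample_ids, name="sample_id")
    _write_table(df, path, header_comment)


def read_similarity(path: str | Path, source: str = "user") -> SimilarityMatrix:
    """Read a K×K similarity TSV with cell-type names as header and index.

    Rows normally sum to 1; a literal uniform-confusion matrix (all row
    sums equal but below 1) is accepted as-is with a logged note.
    """
    df = _read_table(path)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ValidationError(f"{path}: similarity row and column labels differ")
    arr = df.to_numpy(dtype=float)
    rowsums = arr.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > 1e-9) and np.allclose(rowsums, rowsums[0]):
        logger.info(
            "%s: rows sum to %.6g, accepting as literal uniform-style matrix",
            path, rowsums[0],
        )
        source = "uniform"
    return SimilarityMatrix(
        [str(c) for c in df.columns], arr, source=source
    )


def write_similarity(
    m: SimilarityMatrix, path: str | Path, header_comment: str | None = None
) -> None:
    df = pd.DataFrame(m.m, index=m.labels, columns=m.labels)
    df.index.name = "cell_type"
    _write_table(df, path, header_comment)


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    """Read cell-level metadata (cell_id, sample_id, cluster [+extras])."""
    df = _read_table(path, index_col=None)
    missing = {"cell_id", "sample_id", "cluster"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_knn_graph(path: str | Path, cells: pd.DataFrame) -> KnnGraph:
    """Read a KNN graph TSV against a cell metadata table.

    Accepts either a two-column edge list (``cell_id<TAB>neighbor_id``) or
    a ragged list (``cell_id<TAB>comma-separated neighbor ids``).
    """
    cell_ids = [str(c) for c in cells["cell_id"]]
    idx = {c: i for i, c in enumerate(cell_ids)}
    neighbors: list[list[int]] = [[] for _ in cell_ids]
    path = Path(path)
    for ln, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if line.startswith("#") or not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{ln}: expected two tab-separated fields")
        src, targets = parts
        if ln == 1 and src in ("cell_id", "source"):
            continue
        if src not in idx:
            raise ValidationError(f"{path}:{ln}: unknown cell id {src!r}")
        for t in targets.split(","):
            t = t.strip()
            if t not in idx:
                raise ValidationError(f"{path}:{ln}: unknown neighbor id {t!r}")
            neighbors[idx[src]].append(idx[t])
    return KnnGraph(
        cell_ids=cell_ids,
        labels=[str(c) for c in cells["cluster"]],
        neighbors=[np.array(nb, dtype=int) for nb in neighbors],
    )


def read_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    return cfg


def write_results(df: pd.DataFrame, path: str | Path,
                  header_comment: str | None = None) -> None:
    _write_table(df, path, header_comment, index=False)
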