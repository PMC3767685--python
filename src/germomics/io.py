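"""Tab-separated readers and writers for every table the pipeline touches.

On-disk dialect
---------------
All files are plain TSV.  An expression matrix has ``entity_id`` in the
first column and one column per measurement, with the header encoding the
column metadata as ``<time label>:<replicate>:<channel>`` (channels:
``alpha``, ``beta``, ``stain``, ``radio``).  Missing cells are the literal
``NA`` or an empty field.  Stage outputs may carry leading ``#`` comment
lines recording the producing stage and its parameters; readers skip them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import (
    CHANNELS,
    AnnotationTable,
    ExpressionMatrix,
    ReplicateDesign,
    TimeGrid,
    _parse_column,
)
from .datasets import group_vocabulary
from .errors import FormatError, ValidationError

MISSING = "NA"


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=[MISSING, ""], keep_default_na=False, **kw
    )


def _comment_header(stage: str, params: dict | None) -> str:
    items = " ".join(f"{k}={v}" for k, v in (params or {}).items())
    return f"# stage={stage} {items}".rstrip() + "\n"


def read_expression_table(path: str | Path, grid: TimeGrid) -> ExpressionMatrix:
    """Read a replicate expression matrix and attach ``grid``.

    Raises :class:`FormatError` for a malformed header or a time label not
    on the grid, :class:`ValidationError` for negative values or duplicate
    entity IDs.  Missing markers become NaN.
    """
    frame = _read_tsv(path, index_col=0, dtype=str)
    cols = []
    for name in frame.columns:
        label, rep, channel = _parse_column(str(name))
        if label not in grid:
            raise FormatError(f"time label {label!r} not in grid {grid.labels}")
        cols.append((label, rep, channel))
    try:
        values = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    if np.nanmin(values.to_numpy(), initial=np.inf) < 0:
        raise ValidationError(f"negative expression value in {path}")
    values.columns = pd.MultiIndex.from_tuples(cols, names=["time", "replicate", "channel"])
    values.index = values.index.astype(str)
    values.index.name = "entity_id"
    if values.index.has_duplicates:
        dupes = values.index[values.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate entity IDs in {path}: {dupes[:5]}")
    return ExpressionMatrix(values, grid)


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, stage: str = "", params: dict | None = None
) -> None:
    frame = matrix.data.copy()
    frame.columns = [f"{t}:{r}:{c}" for t, r, c in frame.columns]
    frame.index.name = "entity_id"
    with open(path, "w") as fh:
        if stage:
            fh.write(_comment_header(stage, params))
        frame.to_csv(fh, sep="\t", na_rep=MISSING)


def read_annotation_table(
    path: str | Path, groups: Iterable[str] | None = None
) -> AnnotationTable:
    """Read a two-column ``entity_id<TAB>group`` table.

    The group vocabulary defaults to the packaged 27-group classification;
    names outside it raise :class:`ValidationError`.
    """
    groups = tuple(groups) if groups is not None else group_vocabulary()
    try:
        frame = _read_tsv(path, header=None, names=["entity_id", "group"], dtype=str)
    except pd.errors.EmptyDataError:
        frame = pd.DataFrame(columns=["entity_id", "group"])
    mapping = pd.Series(
        frame["group"].to_numpy(), index=frame["entity_id"].astype(str), dtype=str
    )
    return AnnotationTable(mapping, groups)


def write_annotation_table(annot: AnnotationTable, path: str | Path) -> None:
    annot.mapping.to_csv(path, sep="\t", header=False)


def read_design_table(path: str | Path) -> ReplicateDesign:
    """Read the per-time-point replicate count table (Table-1 layout)."""
    frame = _read_tsv(path, index_col=0)
    frame.index = frame.index.astype(str)
    for col in frame.columns:
        vals = frame[col]
        if not np.issubdtype(vals.dtype, np.number) or (vals != vals.astype(int)).any():
            raise ValidationError(f"non-integer count in column {col!r}")
    return ReplicateDesign(frame)


def write_design_table(design: ReplicateDesign, path: str | Path) -> None:
    out = design.counts.copy()
    out.index.name = "time"
    out.to_csv(path, sep="\t")


def read_profile_table(path: str | Path, grid: TimeGrid) -> pd.DataFrame:
    """Read a profiles TSV (entities x time labels) written by a stage."""
    frame = _read_tsv(path, index_col=0)
    frame.index = frame.index.astype(str)
    keep = [c for c in frame.columns if c in grid.labels]
    return frame[keep]


def write_profile_table(
    profiles: pd.DataFrame, path: str | Path, stage: str = "", params: dict | None = None
) -> None:
    with open(path, "w") as fh:
        if stage:
            fh.write(_comment_header(stage, params))
        profiles.to_csv(fh, sep="\t", na_rep=MISSING)


def read_id_list(path: str | Path) -> list[str]:
    """One entity ID per line; ``#`` comments and blank lines ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
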