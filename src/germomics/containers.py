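"""Core in-memory containers shared by every pipeline stage.

The experiment sampled *Streptomyces coelicolor* germination at 13 time
points (dormant spores, then 0 to 5.5 h in 30-min steps).  Three parallel
datasets exist per time point: Sypro-Ruby-stained 2DE gels (accumulated
protein), pulse-radiolabeled 2DE gels (protein synthesis rate; the dormant
point cannot be radiolabeled and is absent), and two-channel microarrays
(sample in the alpha/Cy3 channel, a pooled all-time-points reference in the
beta/Cy5 channel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: channel tags an ExpressionMatrix column may carry
CHANNELS = ("alpha", "beta", "stain", "radio")

#: label of the dormant-spore time point
DORMANT = "dormant"


@dataclass(frozen=True)
class TimeGrid:
    """Ordered time points of one experiment.

    ``hours[i]`` is the numeric hour of ``labels[i]``; the dormant point has
    no numeric hour and carries ``None``.
    """

    labels: tuple[str, ...]
    hours: tuple[float | None, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.hours):
            raise ValidationError("labels and hours differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("time labels must be unique")
        numeric = [h for h in self.hours if h is not None]
        if any(b <= a for a, b in zip(numeric, numeric[1:])):
            raise ValidationError("numeric hours must be strictly increasing")
        for lab, h in zip(self.labels, self.hours):
            if (h is None) != (lab == DORMANT):
                raise ValidationError(
                    f"label {lab!r} / hour {h!r}: only {DORMANT!r} lacks an hour"
                )

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def has_dormant(self) -> bool:
        return DORMANT in self.labels

    def drop_dormant(self) -> "TimeGrid":
        keep = [i for i, lab in enumerate(self.labels) if lab != DORMANT]
        return TimeGrid(
            tuple(self.labels[i] for i in keep), tuple(self.hours[i] for i in keep)
        )

    def shared_labels(self, other: "TimeGrid") -> list[str]:
        """Labels present in both grids, in this grid's order."""
        return [lab for lab in self.labels if lab in other.labels]

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "TimeGrid":
        labels = tuple(labels)
        hours = tuple(None if lab == DORMANT else float(lab) for lab in labels)
        return cls(labels, hours)

    @classmethod
    def germination(cls) -> "TimeGrid":
        """The 13-point germination grid: dormant plus 0–5.5 h every 30 min."""
        labels = (DORMANT,) + tuple(f"{h / 2:.1f}" for h in range(12))
        return cls.from_labels(labels)


def _parse_column(name: str) -> tuple[str, int, str]:
    parts = name.split(":")
    if len(parts) != 3:
        raise FormatError(
            f"column header {name!r} is not of the form label:replicate:channel"
        )
    label, rep, channel = parts
    if channel not in CHANNELS:
        raise FormatError(f"unknown channel {channel!r} in column {name!r}")
    try:
        rep_i = int(rep)
    except ValueError as exc:
        raise FormatError(f"replicate index {rep!r} in column {name!r}") from exc
    return label, rep_i, channel


@dataclass
class ExpressionMatrix:
    """Raw per-replicate measurements for entities (genes or gel spots).

    ``data`` is indexed by entity ID; its columns form a MultiIndex
    ``(time label, replicate index, channel)``.  Values are nonnegative
    fluorescence/radioactivity units, NaN marking missing cells.
    """

    data: pd.DataFrame
    grid: TimeGrid

    def __post_init__(self) -> None:
        cols = self.data.columns
        if not isinstance(cols, pd.MultiIndex) or cols.nlevels != 3:
            raise ValidationError("columns must be a (time, replicate, channel) MultiIndex")
        self.data.columns = cols.set_names(["time", "replicate", "channel"])
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate entity IDs: {dupes[:5]}")
        for lab in cols.get_level_values("time"):
            if lab not in self.grid:
                raise FormatError(f"time label {lab!r} not in the attached grid")
        for ch in cols.get_level_values("channel"):
            if ch not in CHANNELS:
                raise ValidationError(f"unknown channel {ch!r}")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValidationError("expression values must be >= 0 or missing")

    @property
    def entity_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def channels(self) -> list[str]:
        return sorted(set(self.data.columns.get_level_values("channel")))

    def channel(self, name: str) -> pd.DataFrame:
        """Columns of one channel, as a (time, replicate) MultiIndex frame."""
        sub = self.data.xs(name, axis=1, level="channel")
        return sub

    def columns_for(self, time: str, channel: str) -> pd.DataFrame:
        sub = self.data.xs(channel, axis=1, level="channel")
        return sub.xs(time, axis=1, level="time", drop_level=False)

    def with_data(self, data: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(data, self.grid)


#: the 27 functional groups of the Sanger classwise annotation
def _load_group_vocabulary() -> tuple[str, ...]:
    from .datasets import functional_group_table

    return tuple(functional_group_table().index)


@dataclass
class AnnotationTable:
    """entity ID -> functional group, over a closed 27-group vocabulary."""

    mapping: pd.Series
    groups: tuple[str, ...] = field(default_factory=_load_group_vocabulary)

    def __post_init__(self) -> None:
        self.mapping = self.mapping.astype(str)
        self.mapping.index = self.mapping.index.astype(str)
        if self.mapping.index.has_duplicates:
            dup = self.mapping[self.mapping.index.duplicated(keep=False)]
            conflicting = dup.groupby(level=0).nunique()
            if (conflicting > 1).any():
                bad = conflicting[conflicting > 1].index.tolist()
                raise ValidationError(f"entities with conflicting groups: {bad[:5]}")
            self.mapping = self.mapping[~self.mapping.index.duplicated()]
        unknown = set(self.mapping) - set(self.groups)
        if unknown:
            raise ValidationError(f"group names outside vocabulary: {sorted(unknown)[:5]}")

    def __len__(self) -> int:
        return len(self.mapping)

    def group_of(self, entity_id: str) -> str:
        return self.mapping[entity_id]

    def members(self, group: str) -> list[str]:
        return list(self.mapping.index[self.mapping == group])

    def counts(self, ids: Iterable[str] | None = None) -> pd.Series:
        """Per-group member counts, over all entities or a subset."""
        sub = self.mapping if ids is None else self.mapping.loc[list(ids)]
        return sub.value_counts().reindex(self.groups, fill_value=0)


@dataclass
class ReplicateDesign:
    """Replicate counts per time point: stained gels, radiolabeled gels, arrays."""

    counts: pd.DataFrame  # index = time labels, columns = stained/radio/arrays

    COLUMNS = ("stained", "radio", "arrays")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.counts.columns)
        if missing:
            raise ValidationError(f"design table lacks columns {sorted(missing)}")
        self.counts = self.counts[list(self.COLUMNS)]
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            frac, _ = np.modf(arr.astype(float))
            if np.any(frac != 0):
                raise ValidationError("replicate counts must be integers")
            self.counts = self.counts.astype(int)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("replicate counts must be >= 0")
        if DORMANT in self.counts.index and self.counts.loc[DORMANT, "radio"] != 0:
            raise ValidationError("dormant spores cannot be radiolabeled")

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def replicates(self, column: str) -> list[int]:
        return list(self.counts[column])


def build_matrix(
    values: Mapping[tuple[str, int, str], Sequence[float]] | pd.DataFrame,
    entity_ids: Sequence[str],
    grid: TimeGrid,
) -> ExpressionMatrix:
    """Assemble an ExpressionMatrix from per-column value sequences."""
    if isinstance(values, pd.DataFrame):
        frame = values
    else:
        frame = pd.DataFrame(
            {col: np.asarray(v, dtype=float) for col, v in values.items()},
            index=list(entity_ids),
        )
        frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    return ExpressionMatrix(frame, grid)
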