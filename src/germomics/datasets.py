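"""Packaged reference tables.

Two small tables ship with the package:

* the Sanger Institute "classwise" functional classification of the
  *S. coelicolor* genome collapsed to its 27 second-level groups, with the
  number of entities per group observed in each of the three experiments
  (fluorescently stained proteome, radiolabeled proteome, microarray mRNA);
* the replicate design of the germination experiment — how many stained
  gels, radiolabeled gels and microarrays were run at each of the 13 time
  points.
"""

from __future__ import annotations

import functools
from importlib import resources

import pandas as pd

from .containers import ReplicateDesign, TimeGrid


def _data_path(name: str):
    return resources.files("germomics.data") / name


@functools.lru_cache(maxsize=None)
def functional_group_table() -> pd.DataFrame:
    """The 27-group functional classification with per-experiment counts.

    Columns ``fluorescent``, ``radio`` and ``mrna`` give the number of
    entities assigned to each group in the stained proteome, the
    radiolabeled proteome and the final filtered transcriptome.
    """
    with resources.as_file(_data_path("functional_groups.tsv")) as p:
        table = pd.read_csv(p, sep="\t", index_col="group")
    return table


def group_vocabulary() -> tuple[str, ...]:
    """Names of the 27 functional groups, in classification order."""
    return tuple(functional_group_table().index)


@functools.lru_cache(maxsize=None)
def replicate_design() -> ReplicateDesign:
    """Replicate counts per time point of the germination experiment."""
    with resources.as_file(_data_path("replicate_design.tsv")) as p:
        counts = pd.read_csv(p, sep="\t", index_col="time")
    counts.index = counts.index.astype(str)
    return ReplicateDesign(counts)


def germination_grid() -> TimeGrid:
    """The 13-point sampling grid: dormant spores, then 0–5.5 h."""
    return TimeGrid.germination()
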