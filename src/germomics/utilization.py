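"""Absolute-expression analysis from the alpha channel.

Because equal RNA amounts were loaded per array and sample repeats were
spread over arrays, the alpha (sample) channel alone supports comparisons
of absolute expression between genes.  Per-gene abundance is the median of
all alpha measurements; the log2-median distribution is partitioned into
quartiles plus the top 5 %, and the time-resolved count of "highly
expressed" genes (above a global quantile threshold) per functional group
yields utilization series — how many genes of each group the cell keeps
highly expressed through germination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AnnotationTable, ExpressionMatrix
from .errors import UsageError

QUARTILE_LABELS = ("I", "II", "III", "IV")


@dataclass
class AbundanceSummary:
    table: pd.DataFrame        # per gene: median, log2_median, quartile, top5
    boundaries: pd.Series      # Q1, Q2, Q3, P95 of the log2-median distribution

    def genes_in_quartile(self, label: str) -> list[str]:
        return list(self.table.index[self.table["quartile"] == label])


@dataclass
class UtilizationSeries:
    counts: pd.DataFrame       # groups x time points, integer counts
    total: pd.Series           # per time point, all groups pooled
    relative: pd.DataFrame     # 100 * group / total per time point
    threshold: float           # raw-signal threshold used
    quantile: float


def abundance_summary(matrix: ExpressionMatrix) -> AbundanceSummary:
    """Per-gene alpha-channel medians with quartile and top-5% labels.

    Quartile boundaries and the 95th percentile come from the log2-median
    distribution (linear interpolation between order statistics).  A gene
    lands in the highest partition whose lower boundary it reaches:
    quartile IV means log2 median >= Q3; the top-5% flag means >= P95.
    Genes without any measurement are excluded.
    """
    alpha = matrix.channel("alpha")
    medians = alpha.median(axis=1, skipna=True)
    medians = medians[np.isfinite(medians) & (medians > 0)]
    if medians.empty:
        raise UsageError("no gene has any positive alpha measurement")
    log2_med = np.log2(medians)
    q1, q2, q3, p95 = np.quantile(log2_med, [0.25, 0.5, 0.75, 0.95])
    labels = np.select(
        [log2_med >= q3, log2_med >= q2, log2_med >= q1],
        ["IV", "III", "II"],
        default="I",
    )
    table = pd.DataFrame(
        {
            "median": medians,
            "log2_median": log2_med,
            "quartile": labels,
            "top5": log2_med >= p95,
        }
    )
    table.index.name = "entity_id"
    boundaries = pd.Series({"Q1": q1, "Q2": q2, "Q3": q3, "P95": p95})
    return AbundanceSummary(table=table, boundaries=boundaries)


def proteome_quartile_crosstab(
    summary: AbundanceSummary, protein_ids: dict[str, list]
) -> pd.DataFrame:
    """Counts of detected proteins per abundance quartile and in the top 5%.

    ``protein_ids`` maps a set name (e.g. ``stained``, ``radio``) to the
    gene IDs whose protein was detected.  Unmapped IDs are counted in the
    ``unmapped`` column.
    """
    rows = {}
    for name, ids in protein_ids.items():
        ids = list(ids)
        mapped = [i for i in ids if i in summary.table.index]
        sub = summary.table.loc[mapped]
        row = {lab: int((sub["quartile"] == lab).sum()) for lab in QUARTILE_LABELS}
        row["top5"] = int(sub["top5"].sum())
        row["unmapped"] = len(ids) - len(mapped)
        rows[name] = row
    return pd.DataFrame(rows).T[list(QUARTILE_LABELS) + ["top5", "unmapped"]]


def _per_time_signal(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Replicate-averaged alpha signal per gene and time (geometric mean)."""
    alpha = matrix.channel("alpha")
    with np.errstate(divide="ignore"):
        logged = np.log(alpha.to_numpy(dtype=float))
    logged[~np.isfinite(logged)] = np.nan
    frame = pd.DataFrame(logged, index=alpha.index, columns=alpha.columns)
    per_time = np.exp(frame.T.groupby(level="time").mean()).T
    return per_time[[lab for lab in matrix.grid.labels if lab in per_time.columns]]


def utilization_series(
    matrix: ExpressionMatrix,
    annot: AnnotationTable,
    threshold_quantile: float = 0.75,
) -> UtilizationSeries:
    """Count highly expressed genes per functional group over time.

    One global threshold — the ``threshold_quantile`` of the pooled
    distribution of all alpha-channel signals (all genes, time points and
    replicates) — is applied to each gene's replicate-averaged signal at
    each time point, with strict inequality.  Relative series divide each
    group's counts by the all-group total and scale by 100; a time point
    with total zero has missing relative values.
    """
    if not 0 < threshold_quantile < 1:
        raise UsageError("threshold_quantile must lie in (0, 1)")
    alpha = matrix.channel("alpha").to_numpy(dtype=float)
    pooled = alpha[np.isfinite(alpha)]
    if pooled.size == 0:
        raise UsageError("alpha channel has no measurements")
    threshold = float(np.quantile(pooled, threshold_quantile))

    signal = _per_time_signal(matrix)
    high = signal.gt(threshold) & signal.notna()
    groups = annot.mapping.reindex(signal.index)
    counts = high.groupby(groups).sum().reindex(annot.groups, fill_value=0).astype(int)
    total = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        relative = 100.0 * counts / total.replace(0, np.nan)
    return UtilizationSeries(
        counts=counts,
        total=total,
        relative=relative,
        threshold=threshold,
        quantile=threshold_quantile,
    )


def threshold_sensitivity(
    matrix: ExpressionMatrix,
    annot: AnnotationTable,
    quantiles: list[float] = (0.25, 0.5, 0.75),
) -> tuple[dict[float, UtilizationSeries], pd.DataFrame]:
    """Utilization series at several thresholds, plus per-group shape
    correlations between every pair of thresholds.

    A robust analysis shows the *shape* of each group's count profile is
    insensitive to where the high-expression threshold sits.
    """
    series = {q: utilization_series(matrix, annot, q) for q in quantiles}
    rows = []
    qs = list(quantiles)
    for i, qa in enumerate(qs):
        for qb in qs[i:]:
            for group in annot.groups:
                a = series[qa].counts.loc[group].to_numpy(dtype=float)
                b = series[qb].counts.loc[group].to_numpy(dtype=float)
                if a.std() == 0 or b.std() == 0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(a, b)[0, 1])
                rows.append((qa, qb, group, r))
    corr = pd.DataFrame(rows, columns=["q_a", "q_b", "group", "r"])
    return series, corr
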