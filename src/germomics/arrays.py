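"""Two-channel microarray normalization into per-gene expression profiles.

Chain: per-cell Log2Ratio = log2(sample alpha / reference beta); per-array
median/MAD centering; symmetric quantile trimming of the most extreme
ratios; outlier-screened averaging of replicate pools per gene and time
point (Dixon's Q for 3–9 values, Peirce's criterion for larger pools);
exponentiation back to the ratio scale; linear interpolation of single
internal gaps; and a low-expression floor at a quantile of the log2 median
alpha signal, with a single-peak rescue for transiently expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, TimeGrid
from .errors import UsageError, ValidationError
from .outliers import DIXON_CRITICAL, dixon_q_outlier, peirce_outliers


@dataclass
class ArrayNormalizationParams:
    trim_quantile: float = 0.02
    qtest_range: tuple[int, int] = (3, 9)
    peirce_min: int = 10
    qtest_confidence: float = 0.95
    filter_quartile: float = 0.25
    peak_sd_factor: float = 3.0   # single-peak rescue margin
    center: bool = True           # per-array median/MAD centering

    def __post_init__(self) -> None:
        if not 0 <= self.trim_quantile < 0.5:
            raise ValidationError("trim_quantile must lie in [0, 0.5)")
        if not 0 < self.filter_quartile < 1:
            raise ValidationError("filter_quartile must lie in (0, 1)")


@dataclass
class NormalizationReport:
    """Per-stage bookkeeping of cell and gene counts."""

    invalid_ratio_cells: int = 0
    trimmed_cells: int = 0
    interpolated_cells: int = 0
    removed_low: list[str] = field(default_factory=list)
    rescued: list[str] = field(default_factory=list)


def log2_ratio(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, int]:
    """Per-cell log2(alpha/beta) for every (time, replicate) array.

    A nonpositive or missing beta flags the cell invalid; a zero alpha
    becomes missing rather than -inf.  Returns the ratio frame (genes x
    (time, replicate)) and the count of invalidated cells.
    """
    alpha = matrix.channel("alpha")
    beta = matrix.channel("beta")
    common = alpha.columns.intersection(beta.columns)
    if common.empty:
        raise UsageError("no paired alpha/beta arrays in the matrix")
    a = alpha[common].to_numpy(dtype=float)
    b = beta[common].to_numpy(dtype=float)
    invalid = ~np.isfinite(b) | (b <= 0) | ~np.isfinite(a)
    zero_alpha = np.isfinite(a) & (a == 0)
    n_invalid = int((invalid & np.isfinite(a)).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.log2(a) - np.log2(b)
    ratios[invalid | zero_alpha] = np.nan
    out = pd.DataFrame(ratios, index=alpha.index, columns=common)
    return out, n_invalid


def center_scale_array(ratios: pd.Series | np.ndarray, name: str = "array") -> np.ndarray:
    """Center one array's Log2Ratios to median 0 and scale to MAD 1.

    MAD is the plain median absolute deviation, without a normal-
    consistency constant.  A degenerate array (MAD 0, or fewer than three
    finite ratios) raises :class:`ValidationError` naming the array.
    """
    vals = np.asarray(ratios, dtype=float)
    finite = np.isfinite(vals)
    if finite.sum() < 3:
        raise ValidationError(f"array {name} has fewer than 3 finite ratios")
    med = np.median(vals[finite])
    mad = np.median(np.abs(vals[finite] - med))
    if mad == 0:
        raise ValidationError(f"array {name} has zero MAD (degenerate)")
    return (vals - med) / mad


def quantile_trim(ratios: np.ndarray, q: float) -> tuple[np.ndarray, int]:
    """Mark values strictly outside the [q, 1-q] quantile band missing.

    Returns the trimmed copy and the number of removed values.
    """
    if not 0 <= q < 0.5:
        raise UsageError("trim quantile must lie in [0, 0.5)")
    vals = np.asarray(ratios, dtype=float).copy()
    finite = np.isfinite(vals)
    if q == 0 or finite.sum() == 0:
        return vals, 0
    lo, hi = np.quantile(vals[finite], [q, 1 - q])
    kill = finite & ((vals < lo) | (vals > hi))
    vals[kill] = np.nan
    return vals, int(kill.sum())


def _screen_pool(pool: np.ndarray, params: ArrayNormalizationParams) -> np.ndarray:
    """Outlier-screened survivors of one replicate pool (log2 values)."""
    n = pool.size
    lo, hi = params.qtest_range
    if lo <= n <= hi:
        idx = dixon_q_outlier(pool, params.qtest_confidence)
        if idx is not None:
            return np.delete(pool, idx)
    elif n >= params.peirce_min:
        removed = peirce_outliers(pool, params.peirce_min)
        if removed:
            return np.delete(pool, list(removed))
    return pool


def average_replicates(
    ratios: pd.DataFrame,
    grid: TimeGrid,
    params: ArrayNormalizationParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average centered, trimmed log2 ratios into per-gene profiles.

    Per gene and time point, the finite log2 values pooled across arrays
    (and any on-array replicate spots) are outlier-screened — Dixon's Q
    for 3–9 values, Peirce's criterion for >= ``peirce_min`` — then
    averaged in the log2 domain and returned on the ratio scale as
    ``2 ** mean`` (a geometric mean).  Returns (profiles, n_contributing),
    both genes x time labels; an empty pool yields a missing value.
    """
    params = params or ArrayNormalizationParams()
    profiles = pd.DataFrame(index=ratios.index, columns=list(grid.labels), dtype=float)
    n_contrib = pd.DataFrame(0, index=ratios.index, columns=list(grid.labels), dtype=int)
    times = ratios.columns.get_level_values("time")
    for label in grid.labels:
        block = ratios.loc[:, times == label].to_numpy(dtype=float)
        if block.size == 0:
            continue
        means = np.full(block.shape[0], np.nan)
        counts = np.zeros(block.shape[0], dtype=int)
        for i in range(block.shape[0]):
            pool = block[i][np.isfinite(block[i])]
            if pool.size == 0:
                continue
            survivors = _screen_pool(pool, params)
            means[i] = survivors.mean()
            counts[i] = survivors.size
        profiles[label] = np.exp2(means)
        n_contrib[label] = counts
    return profiles, n_contrib


def interpolate_internal_missing(profiles: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Fill single internal gaps by linear interpolation in time-index space.

    Only a missing value whose immediate neighbors on both sides are
    observed is filled; leading/trailing gaps and runs of two or more stay
    missing.  Returns the filled frame and the number of filled cells.
    """
    vals = profiles.to_numpy(dtype=float).copy()
    missing = ~np.isfinite(vals)
    if vals.shape[1] >= 3:
        inner = missing[:, 1:-1] & ~missing[:, :-2] & ~missing[:, 2:]
        rows, cols = np.nonzero(inner)
        cols = cols + 1
        vals[rows, cols] = 0.5 * (vals[rows, cols - 1] + vals[rows, cols + 1])
        n_filled = rows.size
    else:
        n_filled = 0
    return pd.DataFrame(vals, index=profiles.index, columns=profiles.columns), n_filled


def _gene_alpha_medians(alpha: pd.DataFrame) -> pd.Series:
    """Median of all alpha-channel measurements per gene (raw units)."""
    return alpha.median(axis=1, skipna=True)


def _single_peak(time_medians: np.ndarray, sd_factor: float) -> int | None:
    """Index of the unique peaked time point, or None.

    A point peaks when it exceeds the mean of the remaining points by more
    than ``sd_factor`` times their standard deviation.
    """
    finite = np.isfinite(time_medians)
    if finite.sum() < 3:
        return None
    peaks = []
    for t in np.nonzero(finite)[0]:
        others = time_medians[finite & (np.arange(time_medians.size) != t)]
        if time_medians[t] > others.mean() + sd_factor * others.std():
            peaks.append(t)
    return peaks[0] if len(peaks) == 1 else None


def low_expression_filter(
    profiles: pd.DataFrame,
    alpha_matrix: ExpressionMatrix,
    params: ArrayNormalizationParams | None = None,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Drop genes whose overall alpha signal is below the expression floor.

    The floor is the ``filter_quartile`` quantile of the distribution of
    log2 per-gene medians over all time points and replicates.  A gene
    below the floor survives only through the single-peak rescue: exactly
    one time point stands out from the rest of its profile and that
    point's raw replicate median clears the floor.  Returns
    (kept profiles, removed IDs, rescued IDs).
    """
    params = params or ArrayNormalizationParams()
    alpha = alpha_matrix.channel("alpha").loc[profiles.index]
    medians = _gene_alpha_medians(alpha)
    no_signal = medians.index[~np.isfinite(medians) | (medians <= 0)].tolist()
    log2_med = np.log2(medians[np.isfinite(medians) & (medians > 0)])
    threshold = float(np.quantile(log2_med, params.filter_quartile))
    raw_threshold = float(2.0 ** threshold)

    below = log2_med.index[log2_med < threshold].tolist()
    per_time = alpha.T.groupby(level="time").median().T  # genes x time, raw medians
    per_time = per_time[[c for c in profiles.columns if c in per_time.columns]]
    rescued: list[str] = []
    for gene in below:
        series = per_time.loc[gene].to_numpy(dtype=float)
        peak = _single_peak(series, params.peak_sd_factor)
        if peak is not None and series[peak] > raw_threshold:
            rescued.append(gene)
    removed = sorted((set(below) - set(rescued)) | set(no_signal))
    kept = profiles.drop(index=removed)
    return kept, removed, rescued


@dataclass
class ArrayNormalizationResult:
    profiles: pd.DataFrame         # kept genes x time labels, ratio scale
    n_contributing: pd.DataFrame   # replicate survivors per gene x time
    report: NormalizationReport


def normalize_arrays(
    matrix: ExpressionMatrix, params: ArrayNormalizationParams | None = None
) -> ArrayNormalizationResult:
    """Full chain from a two-channel replicate matrix to expression profiles."""
    params = params or ArrayNormalizationParams()
    report = NormalizationReport()
    ratios, report.invalid_ratio_cells = log2_ratio(matrix)
    centered = ratios.copy()
    for col in ratios.columns:
        vals = ratios[col].to_numpy()
        if params.center:
            vals = center_scale_array(vals, name=str(col))
        trimmed, n_trim = quantile_trim(vals, params.trim_quantile)
        centered[col] = trimmed
        report.trimmed_cells += n_trim
    profiles, n_contrib = average_replicates(centered, matrix.grid, params)
    profiles, report.interpolated_cells = interpolate_internal_missing(profiles)
    kept, removed, rescued = low_expression_filter(profiles, matrix, params)
    report.removed_low = removed
    report.rescued = rescued
    return ArrayNormalizationResult(
        profiles=kept, n_contributing=n_contrib.loc[kept.index], report=report
    )
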