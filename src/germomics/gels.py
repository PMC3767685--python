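"""Normalization of 2DE gel spot-intensity tables.

Spot intensities are first divided by the total protein loaded per gel.
Distribution-matching multiplicative factors are then computed from the
stained (accumulative) gels only: assuming log intensities are normally
distributed around a common mean, each gel g with mean log intensity m_g
receives the factor f_g = exp(M - m_g), M being the grand mean of the m_g.
The same stained-gel factors are transferred to the paired radiolabeled
images — early radiolabeled gels carry only a handful of spots, and
normalizing them by their own cumulative signal would inflate the first
time points.  Replicate coefficients of variation quantify the residual
spread.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import UsageError, ValidationError

#: a gel is identified by its (time label, replicate index) pair
GelID = tuple[str, int]


@dataclass
class GelFactorSet:
    """Per-gel multiplicative factors f_g = exp(M - m_g) and the grand mean M."""

    factors: pd.Series        # index = GelID
    log_means: pd.Series      # m_g, natural-log units
    grand_mean: float         # M

    def factor(self, gel: GelID) -> float:
        return float(self.factors[gel])


def _gel_columns(matrix: ExpressionMatrix, channel: str) -> pd.DataFrame:
    if channel not in matrix.channels:
        raise UsageError(f"matrix has no {channel!r} channel")
    return matrix.channel(channel)


def loading_correct(
    matrix: ExpressionMatrix, loadings: Mapping[GelID, float]
) -> ExpressionMatrix:
    """Divide each gel column by the total protein concentration loaded.

    ``loadings`` maps (time label, replicate) to a positive concentration;
    the same divisor applies to every channel of that gel.  Missing cells
    stay missing.
    """
    for gel, value in loadings.items():
        if not value > 0:
            raise ValidationError(f"loading for gel {gel} must be > 0, got {value}")
    data = matrix.data.copy()
    for col in data.columns:
        gel = (col[0], col[1])
        if gel not in loadings:
            raise ValidationError(f"no loading value for gel {gel}")
        data[col] = data[col] / loadings[gel]
    return matrix.with_data(data)


def compute_gel_factors(stained: ExpressionMatrix, channel: str = "stain") -> GelFactorSet:
    """Distribution-matching factors from the stained gels.

    m_g = mean natural-log of the positive spot intensities of gel g,
    M = mean over gels of m_g, f_g = exp(M - m_g).  Zero or missing spots
    are excluded from m_g; a gel without any positive spot is an error.
    """
    cols = _gel_columns(stained, channel)
    log_means = {}
    for col in cols.columns:
        vals = cols[col].to_numpy(dtype=float)
        pos = vals[np.isfinite(vals) & (vals > 0)]
        if pos.size == 0:
            raise ValidationError(f"gel {col} has no positive spots")
        log_means[col] = float(np.mean(np.log(pos)))
    m = pd.Series(log_means)
    M = float(m.mean())
    return GelFactorSet(factors=np.exp(M - m), log_means=m, grand_mean=M)


def apply_gel_factors(
    matrix: ExpressionMatrix, factors: GelFactorSet, transfer: bool = True
) -> ExpressionMatrix:
    """Multiply stained — and, with ``transfer``, radiolabeled — columns by
    the stained gel's factor.

    A radiolabeled column is always scaled by its *paired stained gel's*
    factor (same time label and replicate index), never by its own signal.
    """
    data = matrix.data.copy()
    for col in data.columns:
        label, rep, ch = col
        gel = (label, rep)
        if ch == "stain":
            data[col] = data[col] * factors.factor(gel)
        elif ch == "radio" and transfer:
            if gel not in factors.factors.index:
                raise ValidationError(
                    f"radiolabeled gel {gel} has no paired stained-gel factor"
                )
            data[col] = data[col] * factors.factor(gel)
    return matrix.with_data(data)


def replicate_cv(matrix: ExpressionMatrix) -> dict[str, pd.DataFrame]:
    """Replicate coefficients of variation per channel.

    For each spot and time point with >= 2 observed replicates, CV is the
    sample standard deviation (n-1) over the mean.  The per-time-point CV
    is the mean over qualifying spots; the overall CV is the mean over time
    points.  Returns, per channel, a frame with rows ``cv`` (per time
    point, NaN where no spot qualifies) and the scalar in ``.attrs['overall']``.
    """
    out: dict[str, pd.DataFrame] = {}
    for ch in matrix.channels:
        sub = matrix.channel(ch)
        per_time = {}
        for label in sub.columns.get_level_values("time").unique():
            block = sub.xs(label, axis=1, level="time")
            vals = block.to_numpy(dtype=float)
            n_obs = np.isfinite(vals).sum(axis=1)
            with np.errstate(invalid="ignore"):
                mean = np.nanmean(np.where(np.isfinite(vals), vals, np.nan), axis=1)
                sd = pd.DataFrame(vals).std(axis=1, ddof=1, skipna=True).to_numpy()
            ok = (n_obs >= 2) & (mean != 0) & np.isfinite(sd)
            per_time[label] = float(np.mean(sd[ok] / mean[ok])) if ok.any() else np.nan
        frame = pd.DataFrame({"cv": per_time}).T
        frame.attrs["overall"] = float(np.nanmean(list(per_time.values())))
        out[ch] = frame
    return out
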