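"""Principal-component extraction of kinetic trends and profile correlation.

Expression profiles are row-standardized (each profile to mean 0, SD 1) so
that only the *shape* of the kinetics matters, then decomposed into
principal components of the time-domain covariance.  The PC loadings
(eigenvectors) are the principal kinetic trends of the dataset; genes
whose standardized profiles correlate positively and significantly with a
loading are said to follow that trend.  Decompositions of different
datasets (transcriptome vs. stained or radiolabeled proteome) are aligned
over their shared time points, including detection of a constant index
shift between component orders — the signature of a dataset carrying an
extra dominant trend, such as the consumption of presynthesized spore
proteins in the stained proteome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DORMANT, TimeGrid
from .errors import UsageError


@dataclass
class StandardizedProfileMatrix:
    """Entities x time matrix with every row at mean 0 and SD 1."""

    values: pd.DataFrame
    grid: TimeGrid
    excluded: list[str]   # constant or incomplete profiles left out

    @property
    def entity_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class PCADecomposition:
    loadings: pd.DataFrame          # time x component, orthonormal columns
    eigenvalues: np.ndarray         # nonincreasing, >= 0
    variance_fractions: np.ndarray  # eigenvalues / total, sums to 1
    scores: pd.DataFrame            # entities x component
    grid: TimeGrid

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def loading(self, component: int) -> pd.Series:
        """1-based component access: ``loading(1)`` is PC1."""
        return self.loadings.iloc[:, component - 1]


@dataclass
class ComponentAlignment:
    pairs: list[tuple[int, int, float]]   # (comp in A, comp in B, |r|), 1-based
    shift: int
    shift_scores: dict[int, float]        # candidate shift -> mean |r|
    correlation: pd.DataFrame             # |r| matrix, A components x B components


def standardize_profiles(
    profiles: pd.DataFrame,
    grid: TimeGrid,
    sample_sd: bool = False,
    log_scale: bool = False,
) -> StandardizedProfileMatrix:
    """Row-standardize complete profiles; exclude the rest.

    Profiles with any missing time point (interpolation only fills single
    internal gaps) or zero variance cannot be standardized and are
    excluded, not fatal.  The population (1/n) SD is the default; the
    choice is invisible to downstream correlations.

    ``log_scale`` takes log2 of the (positive, ratio-scale) profile values
    first.  Multiplicative measurement noise is homoscedastic on that
    scale and a gene following a kinetic trend is exactly affine in the
    trend there, so log-scale standardization is the appropriate setting
    for component-recovery analyses; the plain ratio scale remains the
    default.
    """
    frame = profiles[list(grid.labels)]
    if log_scale:
        with np.errstate(divide="ignore", invalid="ignore"):
            frame = np.log2(frame.where(frame > 0))
    vals = frame.to_numpy(dtype=float)
    complete = np.isfinite(vals).all(axis=1)
    sd = vals.std(axis=1, ddof=1 if sample_sd else 0)
    ok = complete & (sd > 0)
    excluded = frame.index[~ok].tolist()
    kept = vals[ok]
    kept = (kept - kept.mean(axis=1, keepdims=True)) / kept.std(
        axis=1, ddof=1 if sample_sd else 0, keepdims=True
    )
    return StandardizedProfileMatrix(
        values=pd.DataFrame(kept, index=frame.index[ok], columns=frame.columns),
        grid=grid,
        excluded=excluded,
    )


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return loadings * flip


def pca_decompose(m: StandardizedProfileMatrix, k: int = 3) -> PCADecomposition:
    """Eigendecomposition of the time-domain covariance of standardized rows.

    Loadings are orthonormal time profiles; the sign of each is fixed so
    its largest-magnitude element is positive (PCA signs are otherwise
    arbitrary).  Variance fractions cover all min(n_time, n_entities)
    components even when only ``k`` loadings are returned.
    """
    X = m.values.to_numpy(dtype=float)
    n, T = X.shape
    if n < 2:
        raise UsageError("at least two profiles are required")
    if k > T:
        raise UsageError(f"k={k} exceeds the {T} time points")
    cov = X.T @ X / n
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = _fix_signs(eigvecs[:, order])
    n_keep = min(T, n)
    eigvals = eigvals[:n_keep]
    fractions = eigvals / eigvals.sum()
    comp_names = [f"PC{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(eigvecs[:, :k], index=m.values.columns, columns=comp_names)
    scores = pd.DataFrame(X @ eigvecs[:, :k], index=m.values.index, columns=comp_names)
    return PCADecomposition(
        loadings=loadings,
        eigenvalues=eigvals,
        variance_fractions=fractions,
        scores=scores,
        grid=m.grid,
    )


def pearson_with_pvalue(x, y) -> tuple[float, float]:
    """Pearson r with its two-sided t-based p-value.

    p derives from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom — the probability of a correlation at least as large in
    magnitude under a true zero correlation.  Degenerate input (zero
    variance, n < 3) yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise UsageError("vectors differ in length")
    n = x.size
    if n < 3:
        return float("nan"), float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan"), float("nan")
    r = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, p


def correlate_with_loading(
    m: StandardizedProfileMatrix,
    d: PCADecomposition,
    component: int = 1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate every profile with one PC loading (1-based index).

    ``significant`` requires p <= alpha *and* r > 0: a gene follows the
    trend.  Negative correlates are recoverable from the sign of r.
    """
    if component > d.k:
        raise UsageError(f"component {component} not among the {d.k} loadings")
    v = d.loading(component).to_numpy()
    X = m.values.to_numpy(dtype=float)
    n = X.shape[1]
    vc = v - v.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc * Xc).sum(axis=1) * (vc @ vc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip((Xc @ vc) / denom, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    out = pd.DataFrame(
        {
            "component": component,
            "r": r,
            "p": p,
            "significant": (p <= alpha) & (r > 0),
        },
        index=m.values.index,
    )
    out.index.name = "entity_id"
    return out


def align_components(
    a: PCADecomposition,
    b: PCADecomposition,
    k: int = 3,
    shift_window: int = 2,
    min_pairs: int = 2,
    drop_dormant: bool = False,
) -> ComponentAlignment:
    """Match components of two decompositions over their shared time points.

    Builds the |Pearson r| matrix between the first ``k`` loadings of each
    dataset (sign-free: loading orientation is arbitrary), pairs them
    greedily by descending |r|, and finds the constant index offset s in
    [-shift_window, +shift_window] maximizing the mean |r| over pairs
    (i, i+s).  A 12-point radiolabeled grid aligns against a 13-point one
    by restricting to the shared labels; ``drop_dormant`` forces the
    dormant point out even when both grids carry it.
    """
    shared = a.grid.shared_labels(b.grid)
    if drop_dormant:
        shared = [lab for lab in shared if lab != DORMANT]
    if len(shared) < 4:
        raise UsageError(f"only {len(shared)} shared time points; >= 4 required")
    ka = min(k, a.k)
    kb = b.k
    corr = np.zeros((ka, kb))
    for i in range(ka):
        va = a.loadings.loc[shared].iloc[:, i].to_numpy()
        for j in range(kb):
            vb = b.loadings.loc[shared].iloc[:, j].to_numpy()
            r, _ = pearson_with_pvalue(va, vb)
            corr[i, j] = abs(r) if np.isfinite(r) else 0.0

    # greedy one-to-one matching by descending |r|
    pairs: list[tuple[int, int, float]] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for i, j in sorted(
        ((i, j) for i in range(ka) for j in range(kb)),
        key=lambda ij: -corr[ij[0], ij[1]],
    ):
        if i not in used_a and j not in used_b:
            pairs.append((i + 1, j + 1, float(corr[i, j])))
            used_a.add(i)
            used_b.add(j)
    pairs.sort()

    # a candidate shift must rest on >= min_pairs matched pairs: a mean
    # over a single pair is not comparable to a mean over several
    shift_scores: dict[int, float] = {}
    for s in range(-shift_window, shift_window + 1):
        vals = [corr[i, i + s] for i in range(ka) if 0 <= i + s < kb]
        if len(vals) >= min(min_pairs, ka):
            shift_scores[s] = float(np.mean(vals))
    # ties break toward the smaller |shift|
    shift = max(sorted(shift_scores, key=abs), key=lambda s: shift_scores[s])
    corr_frame = pd.DataFrame(
        corr,
        index=[f"A{i + 1}" for i in range(ka)],
        columns=[f"B{j + 1}" for j in range(kb)],
    )
    return ComponentAlignment(
        pairs=pairs, shift=int(shift), shift_scores=shift_scores, correlation=corr_frame
    )
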