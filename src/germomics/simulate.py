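"""Synthetic germination datasets with planted, recoverable ground truth.

The generator emulates the structure of the real experiment: a two-channel
transcriptome (sample in the alpha channel, a pooled all-time-points
reference in the beta channel) over the 13-point germination grid, and a
parallel 2DE-gel proteome (stained + radiolabeled channels, fewer entities,
abundance-biased spot sampling, no dormant point in the radiolabeled data).

Generative model
----------------
Each gene *i* has a lognormal baseline abundance ``b_i`` and is assigned to
at most one latent kinetic component ``v_c`` (an orthonormal, mean-zero
time profile).  The noise-free sample signal is

    alpha_i(t) = b_i * 2 ** (a_i * v_c(t))

with a per-gene amplitude ``a_i`` (log2 units); the reference signal is the
gene's own time-average of alpha (the pooled-reference design).  Measured
cells multiply in lognormal noise with a chosen coefficient of variation,
sporadic x10 outlier spikes, and missing values.  The planted log2 ratio of
a follower gene is therefore an exact affine image of its component
profile, so PCA of standardized profiles can recover the planted loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import DORMANT, ExpressionMatrix, AnnotationTable, TimeGrid
from .datasets import functional_group_table, germination_grid
from .errors import ConfigError


# --------------------------------------------------------------------------
# planted component profiles


def _sign_fix(v: np.ndarray) -> np.ndarray:
    """Flip so the element of largest magnitude is positive."""
    return v * np.sign(v[np.argmax(np.abs(v))])


def orthonormal_components(raw: np.ndarray) -> np.ndarray:
    """Center, Gram-Schmidt-orthogonalize and unit-normalize columns.

    Mean-zero columns are used so that planted components live in the same
    subspace PCA of row-standardized profiles explores; this makes exact
    recovery possible in the noise-free limit.
    """
    raw = np.asarray(raw, dtype=float)
    out = np.empty_like(raw)
    for j in range(raw.shape[1]):
        v = raw[:, j] - raw[:, j].mean()
        for i in range(j):
            v = v - (v @ out[:, i]) * out[:, i]
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            raise ConfigError(f"component {j} is degenerate after orthogonalization")
        out[:, j] = _sign_fix(v / norm)
    return out


def default_component_profiles(grid: TimeGrid, k: int = 3) -> np.ndarray:
    """Three germination-like kinetic shapes on ``grid``.

    Component 1 dips right after germination triggering then rises
    steadily; component 2 peaks near 1 h; component 3 starts high and
    rises again late.  Shapes are qualitative stand-ins for the principal
    trends seen in germinating spores.
    """
    t = np.arange(len(grid), dtype=float)
    T = len(grid)
    shapes = [
        np.interp(t, [0, 1, T - 1], [0.5, -1.5, 1.7]),
        np.exp(-((t - T / 4.0) ** 2) / (2 * (T / 8.0) ** 2)),
        np.interp(t, [0, 0.4 * T, 0.75 * T, T - 1], [2.0, -0.6, -0.5, 1.4]),
    ]
    extra = k - len(shapes)
    for j in range(max(0, extra)):
        shapes.append(np.cos((j + 3) * np.pi * t / (T - 1)))
    return orthonormal_components(np.column_stack(shapes[:k]))


def consumption_profile(grid: TimeGrid) -> np.ndarray:
    """Stored-protein consumption shape: strict decline over the first four
    intervals (about the first two hours), then a constant level."""
    t = np.arange(len(grid), dtype=float)
    raw = np.interp(t, [0, 4, len(grid) - 1], [2.0, 0.0, 0.0])
    return raw


# --------------------------------------------------------------------------
# configuration


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic germination experiment.

    Defaults mirror the real design: 13 time points, 3 replicates per time
    point, three latent kinetic components with planted variance shares in
    ratio 0.5 : 0.3 : 0.2, followed by 25/15/10 % of the genes — roughly
    half the transcriptome structured, half unstructured, as in germinating
    spores where the PC1–PC3 follower sets together cover about half the
    expressed genes.  The unstructured bulk is what median/MAD array
    centering anchors on.  Abundances are lognormal over ~3 decades; cells
    carry 20 % multiplicative noise, sparse x10 outlier spikes and sparse
    missing values.  Arrays additionally carry the technical artifacts the
    normalization is built to remove: a per-array additive Log2Ratio offset
    and a per-array gain; gels carry a per-gel brightness factor shared by
    the stained and radiolabeled image of the same gel.
    """

    n_genes: int = 2000
    grid: TimeGrid = field(default_factory=germination_grid)
    replicates: int | Sequence[int] = 3
    n_components: int = 3
    component_profiles: np.ndarray | None = None  # (time, component), orthonormal
    loading_fractions: tuple[float, ...] = (0.25, 0.15, 0.10)
    signal_log2_mean: float = 1.2
    signal_log2_sd: float = 0.3
    signed_amplitudes: bool = False   # followers split between +/- the profile
    abundance_log_mean: float = 7.0   # natural-log units of fluorescence
    abundance_log_sd: float = 1.5
    noise_cv: float = 0.2
    outlier_rate: float = 0.005
    missing_rate: float = 0.01
    array_offset_log2_sd: float = 0.3   # per-array additive shift of Log2Ratios
    array_scale_sd: float = 0.15        # per-array gain on Log2Ratios (lognormal)
    gel_brightness_log_sd: float = 0.4  # per-gel multiplicative brightness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < self.n_components:
            raise ConfigError("n_genes must be >= n_components")
        for name in ("noise_cv", "outlier_rate", "missing_rate"):
            val = getattr(self, name)
            if name != "noise_cv" and not 0 <= val <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if len(self.loading_fractions) != self.n_components:
            raise ConfigError("one loading fraction per component is required")
        if any(f < 0 for f in self.loading_fractions) or sum(self.loading_fractions) > 1 + 1e-12:
            raise ConfigError("loading fractions must be >= 0 and sum to <= 1")
        if self.component_profiles is None:
            self.component_profiles = default_component_profiles(
                self.grid, self.n_components
            )
        prof = np.asarray(self.component_profiles, dtype=float)
        if prof.shape != (len(self.grid), self.n_components):
            raise ConfigError("component_profiles must be (n_time, n_components)")
        gram = prof.T @ prof
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise ConfigError("component profiles must be orthonormal")
        self.component_profiles = prof

    @property
    def replicate_counts(self) -> list[int]:
        if isinstance(self.replicates, int):
            return [self.replicates] * len(self.grid)
        counts = list(self.replicates)
        if len(counts) != len(self.grid):
            raise ConfigError("per-time-point replicate list length mismatch")
        return counts


@dataclass
class GroundTruth:
    """Planted structure of one simulated dataset."""

    component_profiles: pd.DataFrame        # time x component
    dominant: pd.Series                     # gene -> component index, -1 = noise gene
    amplitude: pd.Series                    # gene -> log2 amplitude (0 for noise genes)
    baseline: pd.Series                     # gene -> abundance (raw units)
    standardized_profiles: pd.DataFrame     # gene x time, mean 0 / SD 1 rows

    def followers(self, component: int) -> list[str]:
        return list(self.dominant.index[self.dominant == component])


def fabricate_annotation(
    n_genes: int, seed: int = 0, prefix: str = "G"
) -> AnnotationTable:
    """Random functional-group labels in the genome-wide mRNA proportions."""
    table = functional_group_table()
    probs = table["mrna"] / table["mrna"].sum()
    rng = np.random.default_rng(seed)
    ids = [f"{prefix}{i:05d}" for i in range(n_genes)]
    groups = rng.choice(table.index.to_numpy(), size=n_genes, p=probs.to_numpy())
    return AnnotationTable(pd.Series(groups, index=ids))


# --------------------------------------------------------------------------
# core generator


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=shape))


def _assign_components(n_genes: int, fractions: Sequence[float]) -> np.ndarray:
    """Deterministic block assignment; remainder are pure-noise genes (-1)."""
    dominant = np.full(n_genes, -1, dtype=int)
    start = 0
    for c, f in enumerate(fractions):
        n_c = int(round(f * n_genes))
        dominant[start : start + n_c] = c
        start += n_c
    return dominant


def _planted_signal(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (dominant, amplitude, baseline, log2-signal matrix genes x time)."""
    n, T = cfg.n_genes, len(cfg.grid)
    dominant = _assign_components(n, cfg.loading_fractions)
    amplitude = np.where(
        dominant >= 0,
        np.clip(rng.normal(cfg.signal_log2_mean, cfg.signal_log2_sd, n), 0.3, None),
        0.0,
    )
    if cfg.signed_amplitudes:
        amplitude = amplitude * rng.choice([-1.0, 1.0], size=n)
    baseline = np.exp(rng.normal(cfg.abundance_log_mean, cfg.abundance_log_sd, n))
    signal = np.zeros((n, T))
    follows = dominant >= 0
    signal[follows] = amplitude[follows, None] * cfg.component_profiles.T[dominant[follows]]
    return dominant, amplitude, baseline, signal


def _standardize_rows(mat: np.ndarray) -> np.ndarray:
    centered = mat - mat.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, keepdims=True)
    out = np.zeros_like(centered)
    np.divide(centered, sd, out=out, where=sd > 0)
    return out


def _make_truth(
    cfg: SimulationConfig,
    ids: list[str],
    dominant: np.ndarray,
    amplitude: np.ndarray,
    baseline: np.ndarray,
    signal: np.ndarray,
) -> GroundTruth:
    labels = list(cfg.grid.labels)
    return GroundTruth(
        component_profiles=pd.DataFrame(
            cfg.component_profiles,
            index=labels,
            columns=[f"PC{c + 1}" for c in range(cfg.n_components)],
        ),
        dominant=pd.Series(dominant, index=ids),
        amplitude=pd.Series(amplitude, index=ids),
        baseline=pd.Series(baseline, index=ids),
        standardized_profiles=pd.DataFrame(
            _standardize_rows(signal), index=ids, columns=labels
        ),
    )


def _corrupt(
    rng: np.random.Generator,
    clean: np.ndarray,
    cv: float,
    outlier_rate: float,
    missing_rate: float,
) -> np.ndarray:
    vals = clean * _lognormal_noise(rng, cv, clean.shape)
    if outlier_rate > 0:
        vals = np.where(rng.random(vals.shape) < outlier_rate, vals * 10.0, vals)
    if missing_rate > 0:
        vals = np.where(rng.random(vals.shape) < missing_rate, np.nan, vals)
    return vals


def simulate_transcriptome(
    cfg: SimulationConfig, annot: AnnotationTable | None = None
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a two-channel replicate microarray dataset.

    The alpha channel carries baseline x planted signal x noise x outliers
    with missing cells; the beta channel carries the gene's pooled-reference
    level with its own noise (no outlier spikes: the reference is a common
    RNA pool).  ``annot`` is only consulted for its gene IDs; pass the
    result of :func:`fabricate_annotation` or ``None`` to use generated IDs.
    """
    rng = np.random.default_rng(cfg.seed)
    ids = (
        list(annot.mapping.index[: cfg.n_genes])
        if annot is not None and len(annot) >= cfg.n_genes
        else [f"G{i:05d}" for i in range(cfg.n_genes)]
    )
    dominant, amplitude, baseline, signal = _planted_signal(cfg, rng)
    clean_alpha = baseline[:, None] * np.exp2(signal)  # genes x time
    reference = clean_alpha.mean(axis=1)  # pooled all-time-points mix
    log_ratio = np.log2(clean_alpha / reference[:, None])  # genes x time

    columns: dict[tuple[str, int, str], np.ndarray] = {}
    for t_idx, (label, n_rep) in enumerate(zip(cfg.grid.labels, cfg.replicate_counts)):
        for rep in range(1, n_rep + 1):
            # per-array technical artifacts: additive Log2Ratio offset, gain
            offset = rng.normal(0.0, cfg.array_offset_log2_sd) if cfg.array_offset_log2_sd else 0.0
            gain = np.exp(rng.normal(0.0, cfg.array_scale_sd)) if cfg.array_scale_sd else 1.0
            observed_alpha = reference * np.exp2(gain * log_ratio[:, t_idx] + offset)
            columns[(label, rep, "alpha")] = _corrupt(
                rng, observed_alpha, cfg.noise_cv, cfg.outlier_rate, cfg.missing_rate
            )
            columns[(label, rep, "beta")] = _corrupt(
                rng, reference, cfg.noise_cv, 0.0, cfg.missing_rate
            )
    frame = pd.DataFrame(columns, index=ids)
    frame.columns = pd.MultiIndex.from_tuples(
        frame.columns, names=["time", "replicate", "channel"]
    )
    matrix = ExpressionMatrix(frame, cfg.grid)
    truth = _make_truth(cfg, ids, dominant, amplitude, baseline, signal)
    return matrix, truth


def simulate_gel_dataset(
    cfg: SimulationConfig,
    truth: GroundTruth,
    n_spots: int,
    abundance_bias: float = 0.0,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a parallel 2DE-gel dataset from a transcriptome's genes.

    Spots are sampled without replacement with probability proportional to
    ``baseline ** abundance_bias`` — a positive bias emulates 2DE gels only
    detecting abundant proteins.  The stained channel covers every time
    point; the radiolabeled channel omits the dormant point, which cannot
    be pulse-labeled.  Spot IDs are the source gene IDs so transcriptome
    and proteome profiles can be paired.
    """
    if n_spots > len(truth.baseline):
        raise ConfigError("n_spots cannot exceed the number of genes")
    if abundance_bias < 0:
        raise ConfigError("abundance_bias must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    base = truth.baseline.to_numpy()
    weights = base.astype(float) ** abundance_bias
    weights = weights / weights.sum()
    chosen = rng.choice(len(base), size=n_spots, replace=False, p=weights)
    ids = [truth.baseline.index[i] for i in chosen]

    gel_cfg = replace(cfg, n_genes=n_spots, seed=cfg.seed)
    dominant, amplitude, _, signal = _planted_signal(gel_cfg, rng)
    baseline = base[chosen]
    clean = baseline[:, None] * np.exp2(signal)

    columns: dict[tuple[str, int, str], np.ndarray] = {}
    for t_idx, (label, n_rep) in enumerate(zip(cfg.grid.labels, gel_cfg.replicate_counts)):
        for rep in range(1, n_rep + 1):
            # per-gel brightness, shared by the stained and radiolabeled
            # image of the same gel — what factor transfer corrects
            bright = (
                np.exp(rng.normal(0.0, cfg.gel_brightness_log_sd))
                if cfg.gel_brightness_log_sd
                else 1.0
            )
            columns[(label, rep, "stain")] = _corrupt(
                rng, clean[:, t_idx] * bright, cfg.noise_cv, cfg.outlier_rate, cfg.missing_rate
            )
            if label != DORMANT:
                columns[(label, rep, "radio")] = _corrupt(
                    rng, clean[:, t_idx] * bright, cfg.noise_cv, cfg.outlier_rate, cfg.missing_rate
                )
    frame = pd.DataFrame(columns, index=ids)
    frame.columns = pd.MultiIndex.from_tuples(
        frame.columns, names=["time", "replicate", "channel"]
    )
    matrix = ExpressionMatrix(frame, cfg.grid)
    gel_truth = _make_truth(gel_cfg, ids, dominant, amplitude, baseline, signal)
    return matrix, gel_truth


def plant_pc_shift(cfg: SimulationConfig, consumption_fraction: float = 0.4) -> SimulationConfig:
    """Derive a gel-dataset config whose leading component is a stored-
    protein consumption profile (decline over ~2 h, then constant).

    The consumption component is prepended with a variance share larger
    than any original component's share, so aligning the gel decomposition
    against the source transcriptome must detect a unit index shift.
    """
    prof = cfg.component_profiles
    raw = np.column_stack([consumption_profile(cfg.grid), prof])
    new_prof = orthonormal_components(raw)
    total = sum(cfg.loading_fractions)
    max_orig = max(cfg.loading_fractions)
    # the prepended component's share of the structured population must
    # exceed every original component's (rescaled) share
    min_cf = max_orig / (total + max_orig) if total > 0 else 0.0
    cf = max(consumption_fraction, min_cf + 0.05)
    f0 = cf * total
    fractions = (f0,) + tuple(f * (1.0 - cf) for f in cfg.loading_fractions)
    return replace(
        cfg,
        n_components=cfg.n_components + 1,
        component_profiles=new_prof,
        loading_fractions=fractions,
        signed_amplitudes=True,
    )
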