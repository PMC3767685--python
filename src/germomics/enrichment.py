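"""Functional-group over-representation of selected gene sets.

Each of the 27 functional groups is tested with a 2x2 chi-square
contingency table (in-group vs. out-group x selected vs. not selected)
against the full set, with the fold over-representation
(n_subset/subset_size) / (n_full/full_size).  No continuity correction and
no multiple-testing adjustment enter the significance call at the default
p <= 0.05; Benjamini-Hochberg adjusted p-values are emitted as an extra
column for users who want them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AnnotationTable
from .errors import ValidationError


def _chi2_2x2(table: np.ndarray) -> tuple[float, float, bool]:
    """Chi-square statistic, p, and an expected-count-<5 flag."""
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), float("nan"), True
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), bool((expected < 5).any())


def enrich(
    selected,
    universe,
    annot: AnnotationTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-group over-representation of ``selected`` within ``universe``.

    Returns one row per group of the annotation vocabulary, sorted by fold
    descending: member counts, fold, chi2, p, BH-adjusted p, significance
    at ``alpha`` and a low-expected-count warning flag.  Groups absent from
    the selected set appear with fold 0; a group absent from the universe
    has no defined fold and is not tested.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        extra = sorted(selected - universe)
        raise ValidationError(f"selected IDs outside the universe: {extra[:5]}")
    missing_annot = universe - set(annot.mapping.index)
    if missing_annot:
        raise ValidationError(
            f"universe IDs without annotation: {sorted(missing_annot)[:5]}"
        )
    n_sel = len(selected)
    n_uni = len(universe)
    counts_sel = annot.counts(selected)
    counts_uni = annot.counts(universe)

    rows = []
    for group in annot.groups:
        a = int(counts_sel[group])                  # selected, in group
        n_full = int(counts_uni[group])
        if n_full == 0:
            rows.append((group, a, n_full, np.nan, np.nan, np.nan, False))
            continue
        table = np.array(
            [[a, n_sel - a], [n_full - a, (n_uni - n_sel) - (n_full - a)]]
        )
        fold = (a / n_sel) / (n_full / n_uni) if n_sel else np.nan
        chi2, p, low = _chi2_2x2(table)
        rows.append((group, a, n_full, fold, chi2, p, low))

    out = pd.DataFrame(
        rows,
        columns=["group", "n_subset", "n_full", "fold", "chi2", "p", "expected_low"],
    ).set_index("group")
    out["subset_size"] = n_sel
    out["full_size"] = n_uni
    tested = out["p"].notna()
    adjusted = np.full(len(out), np.nan)
    if tested.any():
        adjusted[tested.to_numpy()] = multipletests(
            out.loc[tested, "p"].to_numpy(), method="fdr_bh"
        )[1]
    out["p_bh"] = adjusted
    out["significant"] = tested & (out["p"] <= alpha)
    return out.sort_values("fold", ascending=False)


def group_correlation_summary(
    results: pd.DataFrame, gene_sets: dict[str, list], alpha: float = 0.05
) -> pd.DataFrame:
    """Fraction of each named gene set significantly correlated with a PC.

    ``results`` is the output of ``correlate_with_loading``.  Fractions are
    reported separately for positive r (the trend followers) and negative r
    at the same p threshold.  Empty sets yield missing fractions.
    """
    rows = []
    for name, ids in gene_sets.items():
        ids = [i for i in ids if i in results.index]
        n = len(ids)
        if n == 0:
            rows.append((name, 0, np.nan, np.nan, 0, 0))
            continue
        sub = results.loc[ids]
        pos = int(((sub["p"] <= alpha) & (sub["r"] > 0)).sum())
        neg = int(((sub["p"] <= alpha) & (sub["r"] < 0)).sum())
        rows.append((name, n, pos / n, neg / n, pos, neg))
    return pd.DataFrame(
        rows,
        columns=["set", "n", "frac_positive", "frac_negative", "n_positive", "n_negative"],
    ).set_index("set")
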