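"""Replicate outlier tests: Dixon's Q (small pools) and Peirce's criterion.

Replicate pools of 3–9 measurements are screened with Dixon's classic Q
ratio (r10 variant, two-sided, one removal per pool); pools of 10 or more
use Peirce's criterion, evaluated through Gould's iterative procedure,
which can reject several observations at once.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import UsageError

#: two-tailed critical values of Dixon's r10 ratio, n = 3..9
DIXON_CRITICAL = {
    0.90: {3: 0.941, 4: 0.765, 5: 0.642, 6: 0.560, 7: 0.507, 8: 0.468, 9: 0.437},
    0.95: {3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568, 8: 0.526, 9: 0.512},
    0.99: {3: 0.994, 4: 0.926, 5: 0.821, 6: 0.740, 7: 0.680, 8: 0.634, 9: 0.598},
}


def dixon_q_outlier(values, confidence: float = 0.95) -> int | None:
    """Index of the single Dixon-flagged outlier, or ``None``.

    Q = gap/range is evaluated at both ends; the more extreme end is
    tested against the two-tailed critical value.  At most one value is
    ever removed per call.  A zero range means no outlier.
    """
    vals = np.asarray(values, dtype=float)
    n = vals.size
    if not 3 <= n <= 9:
        raise UsageError(f"Dixon's Q test applies to 3-9 values, got {n}")
    if confidence not in DIXON_CRITICAL:
        raise UsageError(f"no critical table for confidence {confidence}")
    order = np.argsort(vals, kind="stable")
    s = vals[order]
    rng = s[-1] - s[0]
    if rng == 0:
        return None
    q_low = (s[1] - s[0]) / rng
    q_high = (s[-1] - s[-2]) / rng
    q, idx = (q_low, order[0]) if q_low >= q_high else (q_high, order[-1])
    if q > DIXON_CRITICAL[confidence][n]:
        return int(idx)
    return None


def peirce_threshold(n_total: int, n_outliers: int, n_unknowns: int = 1) -> float:
    """Gould's maximum allowable |deviation|/sigma ratio for Peirce's criterion.

    Solves Peirce's system for ``n_outliers`` doubtful observations among
    ``n_total`` with ``n_unknowns`` fitted quantities, by fixed-point
    iteration on Gould's formulation.  Returns x such that observations
    with |deviation| > x * sigma are rejected.
    """
    N = float(n_total)
    k = float(n_outliers)
    m = float(n_unknowns)
    if N - m - k <= 0:
        raise UsageError("too many suspected outliers for the sample size")
    Q = (k ** (k / N) * (N - k) ** ((N - k) / N)) / N
    r_new, r_old = 1.0, 0.0
    x2 = 0.0
    while abs(r_new - r_old) > N * 2.0e-16:
        ldiv = r_new ** k if r_new ** k != 0 else 1e-300
        lam = ((Q ** N) / ldiv) ** (1.0 / (N - k))
        x2 = 1.0 + (N - m - k) / k * (1.0 - lam * lam)
        if x2 < 0:
            x2 = 0.0
            r_old = r_new
        else:
            r_old = r_new
            r_new = math.exp((x2 - 1.0) / 2.0) * math.erfc(math.sqrt(x2) / math.sqrt(2.0))
    return math.sqrt(x2)


def peirce_outliers(values, min_n: int = 10) -> set[int]:
    """Indices rejected by Peirce's criterion (Gould's procedure).

    Mean and sample standard deviation are taken from the full data; the
    assumed outlier count k starts at 1 and is incremented while more than
    k observations exceed the allowable deviation, until the flagged set
    stabilizes.
    """
    vals = np.asarray(values, dtype=float)
    n = vals.size
    if n < min_n:
        raise UsageError(f"Peirce's criterion requires >= {min_n} values, got {n}")
    mean = vals.mean()
    sigma = vals.std(ddof=1)
    if sigma == 0:
        return set()
    dev = np.abs(vals - mean)
    k = 1
    flagged = np.zeros(n, dtype=bool)
    while n - 1 - k > 0:
        x = peirce_threshold(n, k)
        new_flagged = dev > x * sigma
        n_out = int(new_flagged.sum())
        flagged = new_flagged
        if n_out <= k:
            break
        k += 1
    return set(np.nonzero(flagged)[0].tolist())
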