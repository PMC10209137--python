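"""G^2 (deviance) test of conditional independence for discrete data.

The statistic is ``2 * sum O * ln(O / E)`` over the x-by-y contingency table
within each stratum of the conditioning set, summed across strata; it equals
twice the sample size times the conditional mutual information and is referred
to a chi-squared distribution.  Degrees of freedom follow the standard
adjustment: strata with empty rows or columns contribute fewer terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2

# minimum average expected count per contingency cell for the chi-squared
# approximation to be trusted; below it the test is flagged degenerate and
# treated as a non-rejection (conservative: prevents spurious edges).
MIN_EXPECTED_PER_CELL = 5.0


@dataclass(frozen=True)
class CITestResult:
    statistic: float
    df: int
    p_value: float
    degenerate: bool = False

    def independent(self, alpha: float) -> bool:
        return self.degenerate or self.p_value > alpha


def _encode(columns: Sequence[np.ndarray], cards: Sequence[int]) -> np.ndarray:
    """Mixed-radix code of several small-integer columns."""
    code = np.zeros(len(columns[0]), dtype=np.int64)
    for col, card in zip(columns, cards):
        code = code * card + col
    return code


def g2_test(data, x: str, y: str, z: Sequence[str] = ()) -> CITestResult:
    """Test x independent of y given the variables in z.

    ``data`` is a pandas DataFrame (or mapping of name -> integer array) whose
    columns take values 0..card-1.  Zero observed cells contribute nothing to
    the statistic; strata where x or y shows fewer than two levels lose the
    corresponding degrees of freedom.  A test whose table is too sparse on
    average (expected count < 5 per cell) is flagged ``degenerate`` and callers
    should treat it as a non-rejection.
    """
    if x == y or x in z or y in z:
        raise ValueError("x, y and z must be distinct")
    xv = np.asarray(data[x], dtype=np.int64)
    yv = np.asarray(data[y], dtype=np.int64)
    zvs = [np.asarray(data[c], dtype=np.int64) for c in z]
    n = len(xv)

    rx = int(xv.max()) + 1 if n else 2
    ry = int(yv.max()) + 1 if n else 2
    rx, ry = max(rx, 2), max(ry, 2)
    rzs = [max(int(v.max()) + 1, 2) if n else 2 for v in zvs]
    n_strata = int(np.prod(rzs)) if rzs else 1

    if n == 0 or n < MIN_EXPECTED_PER_CELL * rx * ry * n_strata:
        return CITestResult(0.0, 1, 1.0, degenerate=True)

    strat = _encode(zvs, rzs) if zvs else np.zeros(n, dtype=np.int64)
    code = (strat * rx + xv) * ry + yv
    counts = np.bincount(code, minlength=n_strata * rx * ry).astype(float)
    tables = counts.reshape(n_strata, rx, ry)

    ns = tables.sum(axis=(1, 2))                      # per-stratum totals
    rows = tables.sum(axis=2)                         # (S, rx)
    cols = tables.sum(axis=1)                         # (S, ry)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = rows[:, :, None] * cols[:, None, :] / ns[:, None, None]
        ratio = np.where(tables > 0, tables / expected, 1.0)
        stat = 2.0 * float(np.sum(tables * np.log(ratio)))

    # df adjustment: per non-empty stratum, (non-empty rows - 1)(non-empty cols - 1)
    nz_rows = (rows > 0).sum(axis=1)
    nz_cols = (cols > 0).sum(axis=1)
    df = int(np.sum(np.maximum(nz_rows - 1, 0) * np.maximum(nz_cols - 1, 0)))
    if df <= 0:
        return CITestResult(0.0, 1, 1.0, degenerate=True)

    stat = max(stat, 0.0)  # guard tiny negative rounding
    return CITestResult(stat, df, float(chi2.sf(stat, df)), degenerate=False)
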