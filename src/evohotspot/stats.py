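"""Contingency and correlation statistics for mutation-effect enrichment.

The central use case is asking whether the substitutions captured in an
evolved cohort are enriched for a predicted property (destabilizing
|ddG|, low conservation score) relative to the universe of all possible
substitutions in the gene, via a 2x2 exact test; chi-square tests of
independence back the competition-assay counts, and Spearman rank
correlations compare fitness measures across media.

The Fisher exact p-value is computed from the hypergeometric pmf over the
whole support of the table (log-gamma based, vectorized).  The two-sided
p follows the point-probability convention: the sum of the probabilities
of all tables with the observed margins whose point probability does not
exceed that of the observed table.  This is the same convention as
``scipy.stats.fisher_exact`` and R's ``fisher.test``, which serve as
independent cross-checks in the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "TestResult",
    "CorrelationResult",
    "enrichment_table",
    "fisher_exact",
    "chi_square_independence",
    "spearman",
]

#: relative slack when comparing point probabilities for the two-sided sum
_POINT_PROB_SLACK = 1e-12


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of non-negative counts.

    Rows are captured / not-captured (or genotype), columns are
    flagged / not-flagged (or condition)::

        [[a, b],
         [c, d]]
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 or x != int(x) for x in counts):
            raise ValueError(f"counts must be non-negative integers, got {counts}")
        if sum(counts) <= 0:
            raise ValueError("grand total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    statistic: float  # odds ratio (Fisher) or X^2 (chi-square)
    p_value: float
    sidedness: str
    dof: int | None = None
    flags: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str = "spearman"
    flags: tuple[str, ...] = field(default=())


def enrichment_table(
    universe: int,
    flagged_in_universe: int,
    captured: int,
    flagged_in_captured: int,
) -> ContingencyTable:
    """Build the capture-vs-flag 2x2 table for an enrichment test.

    ``universe`` is the number of possible events (e.g. all possible
    missense substitutions in the gene), ``flagged_in_universe`` how many
    of those carry the predicted property, ``captured`` how many events
    the dataset observed, and ``flagged_in_captured`` how many observed
    events carry the property.  The table is::

        [[flagged&captured,            captured & not flagged        ],
         [flagged & not captured,      neither                       ]]
    """
    if not 0 <= flagged_in_captured <= captured <= universe:
        raise ValueError(
            "need 0 <= flagged_in_captured <= captured <= universe, got "
            f"{flagged_in_captured}, {captured}, {universe}"
        )
    if not flagged_in_captured <= flagged_in_universe <= universe:
        raise ValueError(
            "need flagged_in_captured <= flagged_in_universe <= universe, got "
            f"{flagged_in_captured}, {flagged_in_universe}, {universe}"
        )
    if captured - flagged_in_captured > universe - flagged_in_universe:
        raise ValueError("more unflagged captures than unflagged events in universe")
    return ContingencyTable(
        a=flagged_in_captured,
        b=captured - flagged_in_captured,
        c=flagged_in_universe - flagged_in_captured,
        d=(universe - flagged_in_universe) - (captured - flagged_in_captured),
    )


def _hypergeom_log_pmf_support(n_row1: int, n_col1: int, total: int):
    """Log-pmf of the a-cell over its support for fixed 2x2 margins."""
    lo = max(0, n_row1 + n_col1 - total)
    hi = min(n_row1, n_col1)
    support = np.arange(lo, hi + 1)
    # log C(n_col1, a) + log C(total-n_col1, n_row1-a) - log C(total, n_row1)
    logpmf = (
        gammaln(n_col1 + 1)
        - gammaln(support + 1)
        - gammaln(n_col1 - support + 1)
        + gammaln(total - n_col1 + 1)
        - gammaln(n_row1 - support + 1)
        - gammaln(total - n_col1 - (n_row1 - support) + 1)
        - (gammaln(total + 1) - gammaln(n_row1 + 1) - gammaln(total - n_row1 + 1))
    )
    return support, logpmf


def fisher_exact(table: ContingencyTable, sidedness: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 table.

    ``sidedness`` is one of ``two-sided`` (default, point-probability
    method), ``greater`` (upper tail on the a-cell) or ``less``.  The
    statistic is the sample odds ratio ``ad/bc`` (``inf`` when ``bc`` is 0
    with ``ad`` > 0, ``nan`` for 0/0).
    """
    if sidedness not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    if a * d == 0 and b * c == 0:
        odds = math.nan
    elif b * c == 0:
        odds = math.inf
    else:
        odds = (a * d) / (b * c)

    flags: tuple[str, ...] = ()
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        # a degenerate margin admits only one table: no evidence either way
        return TestResult(odds, 1.0, sidedness, flags=("degenerate-margins",))

    support, logpmf = _hypergeom_log_pmf_support(a + b, a + c, table.total)
    pmf = np.exp(logpmf)
    idx = a - support[0]
    if sidedness == "greater":
        p = float(pmf[idx:].sum())
    elif sidedness == "less":
        p = float(pmf[: idx + 1].sum())
    else:
        cutoff = pmf[idx] * (1.0 + _POINT_PROB_SLACK)
        p = float(pmf[pmf <= cutoff].sum())
    return TestResult(odds, min(p, 1.0), sidedness, flags=flags)


def chi_square_independence(
    table: ContingencyTable, yates: bool = False
) -> TestResult:
    """Chi-square test of independence on a 2x2 table.

    No continuity correction by default; pass ``yates=True`` for the
    corrected statistic.  Expected counts of zero (a zero margin) make
    the statistic undefined and are flagged with p = NaN.
    """
    arr = table.as_array()
    row = arr.sum(axis=1)
    col = arr.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        return TestResult(math.nan, math.nan, "two-sided", dof=1, flags=("zero-expected",))
    chi2, p, dof, _ = sps.chi2_contingency(arr, correction=yates)
    return TestResult(float(chi2), float(p), "two-sided", dof=int(dof))


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p by full enumeration of rank permutations."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    rx = (rx - rx.mean()) / rx.std()
    ry_c = ry - ry.mean()
    denom = math.sqrt((ry_c**2).sum())
    count = 0
    total = 0
    threshold = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = float(np.dot(rx, ry_c[list(perm)])) / (n * denom / math.sqrt(n))
        if abs(r) >= threshold:
            count += 1
        total += 1
    return count / total


def spearman(x, y, exact_max_n: int = 9) -> CorrelationResult:
    """Spearman rank correlation with an exact small-sample p-value.

    rho is the Pearson correlation of the (tie-averaged) ranks.  For
    n <= ``exact_max_n`` the two-sided p-value is exact, by enumeration of
    all n! rank permutations; above that a t-approximation
    t = rho*sqrt((n-2)/(1-rho^2)) is used (this is scipy's default).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(math.nan, math.nan, n, flags=("zero-variance",))
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    if n <= exact_max_n:
        p = _exact_spearman_p(x, y, rho)
        return CorrelationResult(rho, p, n, method="spearman-exact")
    return CorrelationResult(rho, float(res.pvalue), n)
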