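"""Hypothesis tests and interval estimates for comparing label sets.

Two procedures are used when benchmarking a grader (a human rater or a
thresholded model) against the expert group:

* a two-sided Fisher exact test on 2x2 success/failure tables, used to ask
  whether the candidate's precision or recall differs from the expert
  group's; and
* a one-sided two-proportion non-inferiority z-test (the operative bound of
  a TOST procedure) with a 5 percentage-point margin, used to ask whether
  the candidate's agreement is at most ``margin`` worse than the agreement
  observed among the experts themselves.

A Wilson score interval backs every reported proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ValidationError

__all__ = [
    "ContingencyTable2x2",
    "NonInferiorityResult",
    "fisher_exact_two_sided",
    "tost_noninferiority_prop",
    "wilson_ci",
]

# R's fisher.test counts a table as "at least as extreme" when its point
# probability is <= observed * (1 + 1e-7); keep that convention so values
# agree with the reference implementation on knife-edge ties.
_FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts ``[[a, b], [c, d]]`` with fixed row/column margins under H0."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValidationError(f"cell {name} must be an integer, got {v!r}")
            if v < 0:
                raise ValidationError(f"cell {name} must be non-negative, got {v}")
        if self.total == 0:
            raise ValidationError("contingency table is all zeros")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class NonInferiorityResult:
    """Outcome of the one-sided two-proportion non-inferiority test.

    ``diff`` is reference proportion minus candidate proportion; H0 states
    the reference is at least ``margin`` better (diff >= margin).  Small
    ``p`` rejects H0, i.e. supports non-inferiority of the candidate.
    """

    diff: float
    margin: float
    z: float
    p: float
    degenerate: bool = False

    def reject(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    (a, b), (c, d) = table
    return ContingencyTable2x2(int(a), int(b), int(c), int(d))


def fisher_exact_two_sided(table) -> tuple[float, float]:
    """Two-sided Fisher exact test for a 2x2 table.

    The p-value sums, over all tables with the observed margins, the
    hypergeometric point probabilities that do not exceed the observed
    table's (within a 1e-7 relative tolerance).  Computed with exact
    integer arithmetic, so it is accurate to the last float digit for any
    table size used here.

    Returns ``(p, odds_ratio)`` where the odds ratio is the sample
    ``(a*d)/(b*c)``: ``inf`` when only the denominator is zero and ``nan``
    when both numerator and denominator vanish.
    """
    t = _as_table(table)
    a, b, c, d = t.a, t.b, t.c, t.d

    num, den = a * d, b * c
    if den > 0:
        odds_ratio = num / den
    else:
        odds_ratio = math.inf if num > 0 else math.nan

    r, s = a + b, c + d  # row margins
    k = a + c            # first column margin
    n = r + s
    if r == 0 or s == 0 or k == 0 or k == n:
        return 1.0, odds_ratio

    lo, hi = max(0, k - s), min(k, r)
    # integer point weights: P(X=x) = w_x / comb(n, k)
    weights = [math.comb(r, x) * math.comb(s, k - x) for x in range(lo, hi + 1)]
    observed = weights[a - lo]
    # w <= observed * (1 + 1e-7), kept exact with integer arithmetic
    scale = 10 ** 7
    cutoff = observed * (scale + 1)
    tail = sum(w for w in weights if w * scale <= cutoff)
    p = tail / math.comb(n, k)
    return min(1.0, p), odds_ratio


def tost_noninferiority_prop(
    x_ref: int,
    n_ref: int,
    x_cand: int,
    n_cand: int,
    margin: float = 0.05,
) -> NonInferiorityResult:
    """Non-inferiority z-test for two independent binomial proportions.

    H0: p_ref - p_cand >= margin (the reference is at least ``margin``
    better).  With unpooled Wald standard error
    ``SE = sqrt(p_ref(1-p_ref)/n_ref + p_cand(1-p_cand)/n_cand)`` the
    statistic is ``z = (d - margin)/SE`` and ``p`` is the standard-normal
    lower tail of ``z``.  Only the operative one-sided bound of the TOST
    pair is computed; the opposite bound is vacuous for this hypothesis.
    """
    for x, n, side in ((x_ref, n_ref, "reference"), (x_cand, n_cand, "candidate")):
        if n <= 0:
            raise ValidationError(f"{side} trial count must be positive, got {n}")
        if not 0 <= x <= n:
            raise ValidationError(f"{side} successes {x} outside [0, {n}]")
    if not 0.0 < margin < 1.0:
        raise ValidationError(f"margin must lie in (0, 1), got {margin}")

    p_ref = x_ref / n_ref
    p_cand = x_cand / n_cand
    d = p_ref - p_cand
    se = math.sqrt(p_ref * (1 - p_ref) / n_ref + p_cand * (1 - p_cand) / n_cand)

    if se == 0.0:
        if d == margin:
            return NonInferiorityResult(d, margin, 0.0, 0.5, degenerate=True)
        if d < margin:
            return NonInferiorityResult(d, margin, -math.inf, 0.0, degenerate=True)
        return NonInferiorityResult(d, margin, math.inf, 1.0, degenerate=True)

    z = (d - margin) / se
    p = _norm_cdf(z)
    return NonInferiorityResult(d, margin, z, p)


def _norm_cdf(z: float) -> float:
    return 0.5 * math.erfc(-z / math.sqrt(2.0))


def wilson_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, clipped to [0, 1]."""
    if n <= 0:
        raise ValidationError(f"trial count must be positive, got {n}")
    if not 0 <= x <= n:
        raise ValidationError(f"successes {x} outside [0, {n}]")
    if not 0.0 < level < 1.0:
        raise ValidationError(f"confidence level must lie in (0, 1), got {level}")

    # normal quantile via the inverse error function relation
    from scipy.special import ndtri

    z = float(ndtri(0.5 + level / 2.0))
    phat = x / n
    denom = 1.0 + z * z / n
    centre = (phat + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
    lo = max(0.0, centre - half)
    hi = min(1.0, centre + half)
    # the interval endpoints are exactly 0 / 1 at degenerate counts
    if x == 0:
        lo = 0.0
    if x == n:
        hi = 1.0
    return lo, hi
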