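"""Exact conditional tests on 2x2 carrier tables, with full discrete P-value supports.

The burden test compares the number of carriers among ``m`` cases and ``n``
controls, conditioning on the total number of carriers ``k``.  Under the null
hypothesis of no association the case-carrier count ``x`` follows a central
hypergeometric distribution, so every test here is exact and its P value takes
only finitely many achievable values.  The full support (achievable P values
with their null probabilities and CDF) is the engine behind the empirical
inflation factor and the discreteness-aware FDR procedures in
:mod:`raresum.calibration`.

Stratified analysis uses the exact Cochran-Mantel-Haenszel (CMH) statistic
``S = sum_i x_i`` over ethnicity strata; its null distribution is the
convolution of the per-stratum hypergeometric PMFs.

Two-sided P values use the minimum-likelihood rule: the sum of null
probabilities of all outcomes whose point probability does not exceed the
observed one (up to a relative tolerance of 1e-7), the dominant convention for
exact conditional tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

Alternative = Literal["two_sided", "greater", "less"]

#: relative tolerance of the minimum-likelihood two-sided rule
_TWO_SIDED_REL_TOL = 1.0 + 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 carrier table conditioned on its margins.

    The table is ``[[x, m - x], [k - x, n - k + x]]``: ``x`` case carriers out
    of ``m`` cases, ``k - x`` control carriers out of ``n`` controls.
    """

    x: int
    m: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if min(self.m, self.n) < 0 or not (0 <= self.k <= self.m + self.n):
            raise ValueError(f"invalid margins m={self.m} n={self.n} k={self.k}")
        lo, hi = self.support_range()
        if not lo <= self.x <= hi:
            raise ValueError(f"x={self.x} outside achievable range [{lo}, {hi}]")

    def support_range(self) -> tuple[int, int]:
        return max(0, self.k - self.n), min(self.m, self.k)

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.x, self.m - self.x], [self.k - self.x, self.n - self.k + self.x]]
        )


@dataclass(frozen=True)
class PValueSupport:
    """The discrete null distribution of an exact test's P value.

    ``pvalues`` are the distinct achievable P values in increasing order,
    ``probs`` their null probabilities and ``cdf`` the running sum
    ``P(P <= pvalues[j])``.  ``outcome_pvalues[s]`` maps each achievable value
    of the test statistic (offset by ``outcome_offset``) to its P value.
    """

    pvalues: np.ndarray
    probs: np.ndarray
    outcome_pvalues: np.ndarray = field(repr=False)
    outcome_probs: np.ndarray = field(repr=False)
    outcome_offset: int = 0

    @property
    def cdf(self) -> np.ndarray:
        return np.cumsum(self.probs)

    @classmethod
    def from_outcomes(
        cls, pvals: np.ndarray, probs: np.ndarray, offset: int = 0
    ) -> "PValueSupport":
        pvals = np.asarray(pvals, dtype=float)
        probs = np.asarray(probs, dtype=float)
        order = np.argsort(pvals, kind="stable")
        distinct: list[float] = []
        mass: list[float] = []
        for p, w in zip(pvals[order], probs[order]):
            if distinct and p == distinct[-1]:
                mass[-1] += w
            else:
                distinct.append(p)
                mass.append(w)
        return cls(
            pvalues=np.array(distinct),
            probs=np.array(mass),
            outcome_pvalues=pvals,
            outcome_probs=probs,
            outcome_offset=offset,
        )

    def pvalue_of(self, statistic: int) -> float:
        idx = statistic - self.outcome_offset
        if not 0 <= idx < len(self.outcome_pvalues):
            raise ValueError(f"statistic {statistic} outside the support")
        return float(self.outcome_pvalues[idx])

    def cdf_at(self, t: float, rel_tol: float = 1e-12) -> float:
        """P(P <= t) under the null, tolerant to float rounding at support points."""
        idx = np.searchsorted(self.pvalues, t * (1.0 + rel_tol), side="right")
        return float(self.cdf[idx - 1]) if idx > 0 else 0.0


def _pvalues_from_pmf(pmf: np.ndarray, alternative: Alternative) -> np.ndarray:
    """Per-outcome P values for a statistic with null PMF ``pmf`` (indexed low..high)."""
    if alternative == "greater":
        # P(S >= s): reversed cumulative sum
        out = np.cumsum(pmf[::-1])[::-1]
    elif alternative == "less":
        out = np.cumsum(pmf)
    elif alternative == "two_sided":
        thresh = pmf[:, None] * _TWO_SIDED_REL_TOL
        out = np.where(pmf[None, :] <= thresh, pmf[None, :], 0.0).sum(axis=1)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return np.minimum(out, 1.0)


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _hypergeom_logpmf(xs: np.ndarray, m: int, n: int, k: int) -> np.ndarray:
    """log P(X = x) for x case carriers out of m cases, k carriers among m+n."""
    return (
        _log_binom(k, xs)
        + _log_binom(m + n - k, m - xs)
        - _log_binom(m + n, m)
    )


def _hypergeom_pmf(m: int, n: int, k: int) -> tuple[np.ndarray, int]:
    """Central hypergeometric PMF of the case-carrier count; returns (pmf, lowest x)."""
    lo, hi = max(0, k - n), min(m, k)
    xs = np.arange(lo, hi + 1)
    pmf = np.exp(_hypergeom_logpmf(xs, m, n, k))
    return pmf / pmf.sum(), lo


def fet_support(
    m: int, n: int, k: int, alternative: Alternative = "two_sided"
) -> PValueSupport:
    """Discrete P-value support of Fisher's exact test for the given margins."""
    if min(m, n, k) < 0 or k > m + n:
        raise ValueError(f"invalid margins m={m} n={n} k={k}")
    pmf, lo = _hypergeom_pmf(m, n, k)
    pvals = _pvalues_from_pmf(pmf, alternative)
    return PValueSupport.from_outcomes(pvals, pmf, offset=lo)


def fet_pvalue(t: ContingencyTable, alternative: Alternative = "two_sided") -> float:
    """Exact conditional P value of a 2x2 carrier table."""
    return fet_support(t.m, t.n, t.k, alternative).pvalue_of(t.x)


@dataclass(frozen=True)
class StratifiedTables:
    """Per-stratum 2x2 carrier tables; the CMH statistic is ``S = sum x_i``."""

    tables: tuple[ContingencyTable, ...]

    def __post_init__(self) -> None:
        if not self.tables:
            raise ValueError("at least one stratum required")

    @property
    def statistic(self) -> int:
        return sum(t.x for t in self.tables)


def cmh_support(
    st: StratifiedTables | Sequence[ContingencyTable],
    alternative: Alternative = "two_sided",
) -> PValueSupport:
    """Exact null distribution of the CMH statistic and the induced P-value support.

    The null PMF of ``S`` is the convolution of the per-stratum central
    hypergeometric PMFs.  With a single stratum this is exactly the Fisher
    support (delegated, so the reduction is bitwise).
    """
    tables = st.tables if isinstance(st, StratifiedTables) else tuple(st)
    if len(tables) == 1:
        t = tables[0]
        return fet_support(t.m, t.n, t.k, alternative)
    pmf, offset = _hypergeom_pmf(tables[0].m, tables[0].n, tables[0].k)
    for t in tables[1:]:
        pmf_i, lo_i = _hypergeom_pmf(t.m, t.n, t.k)
        pmf = np.convolve(pmf, pmf_i)
        offset += lo_i
    pmf = pmf / pmf.sum()  # guard against convolution rounding drift
    pvals = _pvalues_from_pmf(pmf, alternative)
    return PValueSupport.from_outcomes(pvals, pmf, offset=offset)


def cmh_pvalue(
    st: StratifiedTables | Sequence[ContingencyTable],
    alternative: Alternative = "two_sided",
) -> float:
    """Exact CMH P value of the observed ``S = sum x_i``."""
    tables = st.tables if isinstance(st, StratifiedTables) else tuple(st)
    support = cmh_support(tables, alternative)
    return support.pvalue_of(sum(t.x for t in tables))


def _tilted_mean(log_psi: float, xs: np.ndarray, logw: np.ndarray) -> float:
    """Mean of the noncentral hypergeometric with weights w_x * psi^x."""
    logits = logw + xs * log_psi
    logits -= logits.max()
    w = np.exp(logits)
    return float((xs * w).sum() / w.sum())


def _solve_conditional_mle(parts: list[tuple[np.ndarray, np.ndarray]], s: int) -> float:
    """psi solving sum of per-stratum tilted means = s (strata share psi)."""

    def gap(log_psi: float) -> float:
        return sum(_tilted_mean(log_psi, xs, logw) for xs, logw in parts) - s

    lo, hi = -1.0, 1.0
    while gap(lo) > 0:
        lo *= 2
        if lo < -700:
            return 0.0
    while gap(hi) < 0:
        hi *= 2
        if hi > 700:
            return float("inf")
    return float(np.exp(brentq(gap, lo, hi, xtol=1e-12)))


def _support_logpmf(t: ContingencyTable) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = t.support_range()
    xs = np.arange(lo, hi + 1)
    return xs.astype(float), _hypergeom_logpmf(xs, t.m, t.n, t.k)


def odds_ratio(t: ContingencyTable) -> float:
    """Conditional maximum-likelihood odds ratio of a single 2x2 table.

    The MLE of psi under the noncentral hypergeometric likelihood (the model
    the exact conditional test is based on), found by solving
    ``E_psi[x] = x_observed`` over the exponentially tilted central PMF.
    Returns ``inf`` (open upper bound) when ``x`` sits at the top of its
    range, ``0.0`` at the bottom and ``nan`` for degenerate margins where the
    support is a single point.
    """
    lo, hi = t.support_range()
    if lo == hi:
        return float("nan")
    if t.x == hi:
        return float("inf")
    if t.x == lo:
        return 0.0
    return _solve_conditional_mle([_support_logpmf(t)], t.x)


def cmh_odds_ratio(st: StratifiedTables | Sequence[ContingencyTable]) -> float:
    """Combined conditional-MLE odds ratio across strata.

    Solves ``sum_i E_psi[x_i] = S`` over the common odds ratio ``psi``, the
    stratified analogue of the single-table conditional MLE.
    """
    tables = st.tables if isinstance(st, StratifiedTables) else tuple(st)
    informative = [t for t in tables if t.support_range()[0] < t.support_range()[1]]
    if not informative:
        return float("nan")
    s = sum(t.x for t in informative)
    s_lo = sum(t.support_range()[0] for t in informative)
    s_hi = sum(t.support_range()[1] for t in informative)
    if s == s_hi:
        return float("inf")
    if s == s_lo:
        return 0.0
    return _solve_conditional_mle([_support_logpmf(t) for t in informative], s)
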