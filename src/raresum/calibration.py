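"""Calibration of discrete exact tests: empirical null sampling, inflation
factors, and FDR control aware of discreteness.

Exact tests on rare-variant carrier tables have heterogeneous, discrete null
distributions: a gene with two carriers genome-wide can only achieve a handful
of P values, and "P = 1" occurs with large probability.  Treating these P
values as U(0,1) biases both the genomic inflation factor and
Benjamini-Hochberg FDR control.  This module instead works from each gene's
exact P-value support (:class:`raresum.exact.PValueSupport`):

* ``sample_null_pvalues`` draws margin-conditional null P values directly from
  each gene's CDF (no re-testing, no phenotype permutation);
* ``estimate_lambda_emp`` regresses observed on *exact-null* expected order
  statistics, yielding an unbiased inflation factor; the two uniform-based
  comparators (``estimate_lambda_trapd``) are provided to demonstrate their
  bias on discrete nulls;
* ``rbh_adjust`` implements resampling-based FDR adjustment with a mean
  (RBH_P) or upper-limit (RBH_UL) estimate of null rejections;
* ``discrete_stepdown_adjust`` implements the adaptive heterogeneous
  step-down procedure for discrete tests built from the support CDFs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .exact import PValueSupport

LambdaMethod = Literal["emp", "q05_095", "two_points"]


@dataclass
class NullPValueMatrix:
    """N replicates x G genes of exact-null P values, with the seed used."""

    pvalues: np.ndarray  # shape (N, G)
    seed: int | None = None

    @property
    def n_replicates(self) -> int:
        return self.pvalues.shape[0]

    @property
    def n_genes(self) -> int:
        return self.pvalues.shape[1]


@dataclass(frozen=True)
class LambdaEstimate:
    method: LambdaMethod
    value: float
    n_points: int


def sample_null_pvalues(
    supports: Sequence[PValueSupport],
    n_replicates: int,
    seed: int | np.random.Generator | None = None,
) -> NullPValueMatrix:
    """Draw exact-null P values for every gene by inverse-CDF sampling.

    Each column g is an i.i.d. sample from gene g's discrete support, so every
    entry is an achievable value of that gene's test.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = np.empty((n_replicates, len(supports)))
    u = rng.random((n_replicates, len(supports)))
    for g, sup in enumerate(supports):
        idx = np.searchsorted(sup.cdf, u[:, g], side="left")
        out[:, g] = sup.pvalues[np.minimum(idx, len(sup.pvalues) - 1)]
    return NullPValueMatrix(
        pvalues=out, seed=seed if isinstance(seed, int) else None
    )


def expected_order_statistics(npm: NullPValueMatrix) -> np.ndarray:
    """Expected sorted null P values: per-rank mean of within-replicate sorts."""
    return np.sort(npm.pvalues, axis=1).mean(axis=0)


def _through_origin_slope(x: np.ndarray, y: np.ndarray) -> float:
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError("degenerate regression: all expected points at P = 1")
    return float(np.dot(x, y) / denom)


def estimate_lambda_emp(
    observed: np.ndarray,
    expected_sorted: np.ndarray,
    quantile: float = 0.95,
) -> LambdaEstimate:
    """Inflation factor from exact-null expected order statistics.

    Both vectors are sorted ascending and converted to -log10; the slope of the
    through-origin least-squares fit of observed on expected over the
    *least-significant* ``quantile`` fraction of ranks (the most significant
    5% by default are excluded, protecting the slope from true signals) is
    the inflation factor.
    """
    observed = np.sort(np.asarray(observed, dtype=float))
    expected_sorted = np.asarray(expected_sorted, dtype=float)
    if observed.shape != expected_sorted.shape:
        raise ValueError("observed and expected must have equal length")
    g = len(observed)
    n_keep = int(np.floor(quantile * g))
    if n_keep < 10:
        raise ValueError(f"only {n_keep} usable points; need at least 10")
    # ascending P order: ranks 0..n_keep-1 from the top (largest P) end
    keep = slice(g - n_keep, g)
    x = -np.log10(expected_sorted[keep])
    y = -np.log10(observed[keep])
    return LambdaEstimate("emp", _through_origin_slope(x, y), n_keep)


def estimate_lambda_trapd(
    observed: np.ndarray,
    variant: Literal["q05_095", "two_points"] = "q05_095",
) -> LambdaEstimate:
    """Uniform-assumption comparator estimators of the inflation factor.

    Both take the expected P value of ascending rank r (1-based) among n tests
    to be r/(n+1), i.e. they assume a continuous U(0,1) null.  ``q05_095``
    fits a through-origin slope over ranks between the 0.5 and 0.95 quantiles;
    ``two_points`` draws the slope through two points on the -log10 QQ plot:
    the inner edge of the P = 1 plateau (the most significant rank still
    observed at 1) and the 0.95 significance quantile among the P values not
    equal to 1.  On discrete exact-test nulls both are biased away from 1.
    """
    observed = np.sort(np.asarray(observed, dtype=float))
    n = len(observed)
    if n == 0:
        raise ValueError("observed is empty")
    expected = np.arange(1, n + 1) / (n + 1)
    if variant == "two_points":
        ones = np.flatnonzero(observed >= 1.0)
        not_ones = np.flatnonzero(observed < 1.0)
        if len(ones) == 0 or len(not_ones) == 0:
            # no P = 1 present (or nothing else): fall back, as documented
            return LambdaEstimate(
                "two_points", estimate_lambda_trapd(observed, "q05_095").value, n
            )
        # ranks on the QQ plot count from the least significant end, so the
        # highest-rank P = 1 point is the first ascending index at 1
        r1 = ones[0]
        # 0.95 quantile on the significance (-log10 P) scale: 5% from the
        # most significant end of the non-1 values
        r2 = not_ones[int(np.floor(0.05 * (len(not_ones) - 1)))]
        x1, y1 = -np.log10(expected[r1]), 0.0
        x2, y2 = -np.log10(expected[r2]), -np.log10(observed[r2])
        if x2 == x1:
            raise ValueError("degenerate two-point configuration")
        return LambdaEstimate("two_points", (y2 - y1) / (x2 - x1), 2)
    if variant != "q05_095":
        raise ValueError(f"unknown variant {variant!r}")
    lo = int(np.floor(0.5 * n))
    hi = int(np.ceil(0.95 * n))
    # band between the 0.5 and 0.95 quantiles of the ascending P values
    idx = slice(lo, hi)
    x = -np.log10(expected[idx])
    y = -np.log10(observed[idx])
    if np.all(y == 0.0):
        raise ValueError("all observed P values in the band equal 1")
    return LambdaEstimate("q05_095", _through_origin_slope(x, y), hi - lo)


def bh_adjust(observed: np.ndarray) -> np.ndarray:
    """Standard Benjamini-Hochberg step-up adjusted P values (baseline)."""
    observed = np.asarray(observed, dtype=float)
    if observed.size == 0:
        raise ValueError("observed is empty")
    return multipletests(observed, method="fdr_bh")[1]


def _null_rejection_counts(
    null_matrix: np.ndarray, thresholds: np.ndarray
) -> np.ndarray:
    """R*(p) for every replicate (rows) and threshold (columns)."""
    sorted_nulls = np.sort(null_matrix, axis=1)
    out = np.empty((null_matrix.shape[0], len(thresholds)), dtype=float)
    for i, row in enumerate(sorted_nulls):
        out[i] = np.searchsorted(row, thresholds, side="right")
    return out


def rbh_adjust(
    observed: np.ndarray,
    npm: NullPValueMatrix,
    variant: Literal["P", "UL"] = "UL",
    beta: float = 0.05,
) -> np.ndarray:
    """Resampling-based FDR adjustment from exact-null replicates.

    For each observed threshold p let R(p) be the number of observed P values
    <= p and R*(p) the same count in a null replicate.  The estimated number
    of true rejections is s(p) = R(p) - M*(p) (variant "P", mean) or
    s(p) = R(p) - Q*_beta(p) (variant "UL", the 1-beta quantile of R*).  The
    adjusted value at p is E[R*/(R* + s)] over replicates when s is large
    enough (s >= Q*_beta for "P", s > 0 for "UL"), else the fraction of
    replicates with any null rejection; the result is made monotone in p and
    capped at 1.
    """
    observed = np.asarray(observed, dtype=float)
    if npm.n_genes != len(observed):
        raise ValueError("null matrix and observed P values must cover the same genes")
    order = np.argsort(observed, kind="stable")
    p_sorted = observed[order]
    big_r = np.arange(1, len(observed) + 1, dtype=float)
    # ties share the largest rank at their value
    for i in range(len(p_sorted) - 2, -1, -1):
        if p_sorted[i] == p_sorted[i + 1]:
            big_r[i] = big_r[i + 1]
    r_star = _null_rejection_counts(npm.pvalues, p_sorted)  # (N, G)
    m_star = r_star.mean(axis=0)
    q_star = np.quantile(r_star, 1.0 - beta, axis=0)
    if variant == "P":
        s = big_r - m_star
        use_ratio = s >= q_star
    elif variant == "UL":
        s = big_r - q_star
        use_ratio = s > 0
    else:
        raise ValueError(f"unknown variant {variant!r}")
    denom = r_star + s[None, :]
    ratio = np.where(denom > 0, r_star / np.where(denom > 0, denom, 1.0), 0.0)
    expected_ratio = ratio.mean(axis=0)
    any_null_rejection = (r_star > 0).mean(axis=0)
    adj = np.where(use_ratio, expected_ratio, any_null_rejection)
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def _support_cdf_matrix(
    supports: Sequence[PValueSupport], thresholds: np.ndarray
) -> np.ndarray:
    """F_g(t) = P(P_g <= t) for every gene g (rows) and threshold t (columns)."""
    out = np.empty((len(supports), len(thresholds)))
    scaled = thresholds * (1.0 + 1e-12)
    for g, sup in enumerate(supports):
        idx = np.searchsorted(sup.pvalues, scaled, side="right")
        cdf = np.concatenate(([0.0], sup.cdf))
        out[g] = cdf[idx]
    return out


def discrete_stepdown_adjust(
    observed: np.ndarray, supports: Sequence[PValueSupport]
) -> np.ndarray:
    """Adaptive discrete step-down FDR adjustment from exact support CDFs.

    The adaptive heterogeneous step-down procedure rejects the k smallest
    P values when p_(j) <= tau_j for all j <= k, with critical constants
    tau_j = max{t in the pooled support : sum of the (G - j + 1) smallest
    F_g(t)/(1 - F_g(t)) <= j * alpha}.  The adjusted value of p_(k) is the
    smallest alpha at which it is rejected,
    max_{j <= k} min(1, (1/j) * sum of the (G - j + 1) smallest
    F_g(p_(j))/(1 - F_g(p_(j)))), which this function returns in the original
    gene order.  F_g(t)/(1 - F_g(t)) is +inf where F_g(t) = 1; those terms are
    the largest and drop out once j - 1 of them may be discarded.
    """
    observed = np.asarray(observed, dtype=float)
    if len(observed) != len(supports):
        raise ValueError("one support per observed P value required")
    g = len(observed)
    order = np.argsort(observed, kind="stable")
    p_sorted = observed[order]
    f = _support_cdf_matrix(supports, p_sorted)  # (G genes, G thresholds)
    with np.errstate(divide="ignore"):
        ratio = np.where(f < 1.0, f / (1.0 - np.where(f < 1.0, f, 0.5)), np.inf)
    ratio_sorted = np.sort(ratio, axis=0)
    csum = np.cumsum(ratio_sorted, axis=0)
    ranks = np.arange(1, g + 1)
    # column j-1 (threshold p_(j)): sum of the (G - j + 1) smallest ratios / j
    crit = csum[g - ranks, np.arange(g)] / ranks
    adj = np.minimum(np.maximum.accumulate(crit), 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def discrete_stepup_adjust(
    observed: np.ndarray, supports: Sequence[PValueSupport]
) -> np.ndarray:
    """Non-adaptive heterogeneous step-up adjustment (sum of all F_g(t) / k).

    In the continuous-uniform limit F_g(t) = t this is exactly the
    Benjamini-Hochberg step-up procedure.
    """
    observed = np.asarray(observed, dtype=float)
    if len(observed) != len(supports):
        raise ValueError("one support per observed P value required")
    g = len(observed)
    order = np.argsort(observed, kind="stable")
    p_sorted = observed[order]
    f = _support_cdf_matrix(supports, p_sorted)
    crit = f.sum(axis=0) / np.arange(1, g + 1)
    # step-up: running minimum from the least significant end
    adj = np.minimum(np.minimum.accumulate(crit[::-1])[::-1], 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out
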