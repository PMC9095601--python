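"""Detection of rare-variant pairs in high linkage disequilibrium from
partitioned summary counts, or from full genotypes.

Two biallelic variants define four haplotypes with probabilities
p11, p10, p01, p00 (1 = alternate allele).  Reparametrize with the marginal
alternate-allele frequencies s = p11 + p10 and t = p11 + p01 and the haplotype
odds ratio

    theta = p11 * p00 / (p10 * p01),

which measures LD strength and direction.  Public resources such as gnomAD can
be split into several *independent* summary-count sets (cancer /
non-cancer-non-control / control, each by sex): given observed alternate
allele counts (x_i, y_i) of the two variants among n_i haplotypes in
independent set i, and assuming Hardy-Weinberg equilibrium within each set,
the likelihood marginalizes the unobserved double-alternate haplotype count r:

    P(x, y | n) = sum_r  n! / (r! (x-r)! (y-r)! (n-x-y+r)!)
                  * p11^r p10^(x-r) p01^(y-r) p00^(n-x-y+r)

with r in [max(0, x+y-n), min(x, y)].  Positive LD (theta > 1) is tested with
a one-sided likelihood-ratio statistic, maximizing over (s, t, theta)
unconstrained versus constrained to theta <= 1, with s and t as nuisance
parameters; the P value uses the chi-square distribution with 1 degree of
freedom.  The additive genotype coding is the special case n = 2, so the same
machinery tests LD from full genotypes (with higher power).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2

from .calibration import bh_adjust

#: box bound on log(theta) during optimization
_LOG_THETA_BOUND = 30.0
#: box bound on logit(s), logit(t)
_LOGIT_BOUND = 30.0


@dataclass(frozen=True)
class SixSetCounts:
    """Allele counts of a variant pair over independent pooled sets.

    ``x[i]`` and ``y[i]`` are the alternate allele counts of the two variants
    among ``n[i]`` haplotypes in independent set i.  ``weights`` allows a set
    to stand for several identical observations (used by the full-genotype
    reduction, where each genotype combination is one n = 2 set).
    """

    x: np.ndarray
    y: np.ndarray
    n: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        x, y, n = (np.asarray(a, dtype=int) for a in (self.x, self.y, self.n))
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "n", n)
        if not (len(x) == len(y) == len(n)) or len(x) == 0:
            raise ValueError("x, y, n must be nonempty and of equal length")
        if np.any(x < 0) or np.any(y < 0) or np.any(x > n) or np.any(y > n):
            raise ValueError("allele counts must satisfy 0 <= x, y <= n")
        if self.weights is not None:
            object.__setattr__(
                self, "weights", np.asarray(self.weights, dtype=float)
            )

    @property
    def informative(self) -> bool:
        return bool(np.any(self.x > 0) and np.any(self.y > 0))


@dataclass(frozen=True)
class HaplotypeModel:
    """Four haplotype probabilities of a variant pair."""

    p11: float
    p10: float
    p01: float
    p00: float

    def __post_init__(self) -> None:
        probs = (self.p11, self.p10, self.p01, self.p00)
        if min(probs) < -1e-9:
            raise ValueError(f"negative haplotype probability: {self}")
        if abs(sum(probs) - 1.0) > 1e-6:
            raise ValueError(f"haplotype probabilities do not sum to 1: {self}")

    @property
    def s(self) -> float:
        return self.p11 + self.p10

    @property
    def t(self) -> float:
        return self.p11 + self.p01

    @property
    def theta(self) -> float:
        if self.p10 == 0.0 or self.p01 == 0.0:
            return float("inf")
        return self.p11 * self.p00 / (self.p10 * self.p01)

    @classmethod
    def from_marginals(cls, s: float, t: float, theta: float) -> "HaplotypeModel":
        p11 = _p11_from_marginals(s, t, theta)
        return cls(
            p11=p11,
            p10=max(s - p11, 0.0),
            p01=max(t - p11, 0.0),
            p00=max(1.0 - s - t + p11, 0.0),
        )


def _p11_from_marginals(s: float, t: float, theta: float) -> float:
    """Unique root of p11*p00 = theta*p10*p01 inside [max(0,s+t-1), min(s,t)]."""
    if not (0.0 < s < 1.0 and 0.0 < t < 1.0):
        raise ValueError("marginal frequencies must lie strictly in (0, 1)")
    if theta <= 0.0:
        raise ValueError("theta must be positive")
    if abs(theta - 1.0) < 1e-12:
        return s * t
    a = theta - 1.0
    b = 1.0 + (s + t) * a
    c = theta * s * t
    disc = max(b * b - 4.0 * a * c, 0.0)
    sq = np.sqrt(disc)
    # smaller root of a*p^2 - b*p + c; the 2c/(b+sq) form avoids the
    # catastrophic cancellation of (b - sq) when 4ac << b^2
    root = 2.0 * c / (b + sq) if b > 0 else (b - sq) / (2.0 * a)
    lo, hi = max(0.0, s + t - 1.0), min(s, t)
    return float(np.clip(root, lo, hi))


def _set_loglik_and_weights(
    x: int, y: int, n: int, logp: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """log P(x, y | n) and the posterior distribution over the latent r."""
    r = np.arange(max(0, x + y - n), min(x, y) + 1)
    counts = np.stack([r, x - r, y - r, n - x - y + r], axis=1)
    log_coef = (
        gammaln(n + 1) - gammaln(counts + 1).sum(axis=1)
    )
    with np.errstate(invalid="ignore"):
        log_terms = log_coef + np.where(
            counts > 0, counts * logp[None, :], 0.0
        ).sum(axis=1)
    log_terms = np.where(
        np.any((counts > 0) & np.isneginf(logp[None, :]), axis=1),
        -np.inf,
        log_terms,
    )
    total = logsumexp(log_terms)
    if np.isneginf(total):
        return float(total), r, np.zeros_like(r, dtype=float)
    return float(total), r, np.exp(log_terms - total)


def loglik_summary(model: HaplotypeModel, data: SixSetCounts) -> float:
    """Summed log-likelihood of the observed pooled counts under ``model``."""
    p = np.array([model.p11, model.p10, model.p01, model.p00])
    with np.errstate(divide="ignore"):
        logp = np.log(p)
    w = data.weights if data.weights is not None else np.ones(len(data.x))
    total = 0.0
    for xi, yi, ni, wi in zip(data.x, data.y, data.n, w):
        ll, _, _ = _set_loglik_and_weights(int(xi), int(yi), int(ni), logp)
        total += wi * ll
    return total


def loglik_summary_grad(
    model: HaplotypeModel, data: SixSetCounts
) -> tuple[float, np.ndarray]:
    """Log-likelihood and its analytic gradient w.r.t. (s, t, log theta).

    The gradient in haplotype space follows from the posterior over the latent
    double-alternate count r: d logP / d p11 = E[r | x, y] / p11 etc.; the
    chain rule through the implicit equation p11*p00 = theta*p10*p01 maps it
    to the (s, t, log theta) scale.
    """
    p = np.array([model.p11, model.p10, model.p01, model.p00])
    with np.errstate(divide="ignore"):
        logp = np.log(p)
    w = data.weights if data.weights is not None else np.ones(len(data.x))
    total = 0.0
    grad_p = np.zeros(4)  # d logL / d (p11, p10, p01, p00), p treated freely
    for xi, yi, ni, wi in zip(data.x, data.y, data.n, w):
        ll, r, post = _set_loglik_and_weights(int(xi), int(yi), int(ni), logp)
        total += wi * ll
        e_r = float(post @ r)
        exp_counts = np.array([e_r, xi - e_r, yi - e_r, ni - xi - yi + e_r])
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(p > 0, exp_counts / p, 0.0)
        grad_p += wi * contrib
    s, t, theta = model.s, model.t, model.theta
    if not np.isfinite(theta):
        # boundary where p10 or p01 vanishes: the log-theta direction is flat
        return total, np.array(
            [grad_p[1] - grad_p[3], grad_p[2] - grad_p[3], 0.0]
        )
    # implicit derivatives of p11(s, t, theta) from
    # G = p11*(1 - s - t + p11) - theta*(s - p11)*(t - p11) = 0
    p11 = model.p11
    dg_dp11 = 1.0 - s - t + 2.0 * p11 + theta * (s + t - 2.0 * p11)
    dg_ds = -p11 - theta * (t - p11)
    dg_dt = -p11 - theta * (s - p11)
    dg_dtheta = -(s - p11) * (t - p11)
    dp11_ds = -dg_ds / dg_dp11
    dp11_dt = -dg_dt / dg_dp11
    dp11_dtheta = -dg_dtheta / dg_dp11
    # p10 = s - p11; p01 = t - p11; p00 = 1 - s - t + p11
    dl_dp11 = grad_p[0] - grad_p[1] - grad_p[2] + grad_p[3]
    dl_ds = grad_p[1] - grad_p[3] + dl_dp11 * dp11_ds
    dl_dt = grad_p[2] - grad_p[3] + dl_dp11 * dp11_dt
    dl_dlogtheta = dl_dp11 * dp11_dtheta * theta
    return total, np.array([dl_ds, dl_dt, dl_dlogtheta])


def loglik_genotype(counts: np.ndarray, model: HaplotypeModel) -> float:
    """Log-likelihood of a 3x3 genotype-combination table under HWE.

    ``counts[i, j]`` is the number of samples with genotype i at the first
    variant and j at the second.  The cell probabilities are the n = 2
    specialization of the pooled-count likelihood, e.g.
    f11 = 2*p11*p00 + 2*p10*p01.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (3, 3) or np.any(c < 0):
        raise ValueError("counts must be a nonnegative 3x3 table")
    p11, p10, p01, p00 = model.p11, model.p10, model.p01, model.p00
    f = np.array(
        [
            [p00**2, 2 * p00 * p01, p01**2],
            [2 * p10 * p00, 2 * p11 * p00 + 2 * p10 * p01, 2 * p11 * p01],
            [p10**2, 2 * p11 * p10, p11**2],
        ]
    )
    with np.errstate(divide="ignore"):
        logf = np.log(f)
    if np.any((c > 0) & np.isneginf(logf)):
        return float("-inf")
    return float(np.where(c > 0, c * logf, 0.0).sum())


def genotype_table_as_sets(counts: np.ndarray) -> SixSetCounts:
    """Represent a 3x3 genotype table as weighted n = 2 pooled-count sets."""
    c = np.asarray(counts, dtype=float)
    xs, ys, ws = [], [], []
    for i in range(3):
        for j in range(3):
            if c[i, j] > 0:
                xs.append(i)
                ys.append(j)
                ws.append(c[i, j])
    if not xs:
        raise ValueError("empty genotype table")
    return SixSetCounts(
        x=np.array(xs), y=np.array(ys), n=np.full(len(xs), 2), weights=np.array(ws)
    )


@dataclass(frozen=True)
class LDTestResult:
    theta_hat: float
    statistic: float
    p_value: float
    s_hat: float
    t_hat: float
    converged: bool = True
    skipped: bool = False


@dataclass(frozen=True)
class LDPair:
    """A tested variant pair."""

    key1: str
    key2: str
    stratum: str
    theta_hat: float
    statistic: float
    p_value: float
    fdr: float = float("nan")
    distance_bp: int | None = None
    high_ld: bool = False


def _logit(p: float) -> float:
    return float(np.log(p) - np.log1p(-p))


def _expit(z: float) -> float:
    return float(1.0 / (1.0 + np.exp(-z)))


def _negloglik_z(z: np.ndarray, data: SixSetCounts) -> tuple[float, np.ndarray]:
    s, t = _expit(z[0]), _expit(z[1])
    theta = float(np.exp(z[2]))
    model = HaplotypeModel.from_marginals(s, t, theta)
    ll, grad = loglik_summary_grad(model, data)
    if not np.isfinite(ll):
        return 1e12, np.zeros(3)
    # chain rule to the unconstrained scale
    g = np.array([grad[0] * s * (1 - s), grad[1] * t * (1 - t), grad[2]])
    return -ll, -g


def _maximize(
    data: SixSetCounts,
    log_theta_max: float,
    starts: Sequence[tuple[float, float, float]],
) -> tuple[float, np.ndarray, bool]:
    bounds = [
        (-_LOGIT_BOUND, _LOGIT_BOUND),
        (-_LOGIT_BOUND, _LOGIT_BOUND),
        (-_LOG_THETA_BOUND, log_theta_max),
    ]
    best_ll, best_z, ok = -np.inf, None, False
    for s0, t0, theta0 in starts:
        z0 = np.array(
            [
                _logit(np.clip(s0, 1e-8, 1 - 1e-8)),
                _logit(np.clip(t0, 1e-8, 1 - 1e-8)),
                np.clip(np.log(theta0), -_LOG_THETA_BOUND, log_theta_max),
            ]
        )
        res = minimize(
            _negloglik_z,
            z0,
            args=(data,),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
        )
        if np.isfinite(res.fun) and -res.fun > best_ll:
            best_ll, best_z, ok = -res.fun, res.x, ok or res.success
    return best_ll, best_z, ok


def _default_starts(data: SixSetCounts) -> list[tuple[float, float, float]]:
    w = data.weights if data.weights is not None else np.ones(len(data.x))
    total_n = float((w * data.n).sum())
    s0 = max(float((w * data.x).sum()) / total_n, 1e-8)
    t0 = max(float((w * data.y).sum()) / total_n, 1e-8)
    return [
        (s0, t0, 1.0),
        (s0, t0, 100.0),
        (s0, t0, 0.1),
        (min(2 * s0, 0.5), min(2 * t0, 0.5), 1000.0),
    ]


def lrt_summary(
    data: SixSetCounts, theta_null_bound: float = 1.0
) -> LDTestResult:
    """One-sided LRT for positive LD from pooled summary counts.

    ``T = 2 (sup_{theta} logL - sup_{theta <= bound} logL)``; the P value is
    the upper tail of chi-square with 1 df at T.  Pairs where either variant
    has no alternate allele anywhere are uninformative and skipped (P = 1).
    """
    if not data.informative:
        return LDTestResult(
            theta_hat=float("nan"),
            statistic=0.0,
            p_value=1.0,
            s_hat=float("nan"),
            t_hat=float("nan"),
            skipped=True,
        )
    starts = _default_starts(data)
    ll_full, z_full, ok_full = _maximize(data, _LOG_THETA_BOUND, starts)
    null_starts = [s for s in starts if s[2] <= theta_null_bound]
    if z_full is not None:
        null_starts = null_starts + [
            (_expit(z_full[0]), _expit(z_full[1]), min(1.0, theta_null_bound))
        ]
    ll_null, _, ok_null = _maximize(
        data, np.log(theta_null_bound), null_starts or starts
    )
    if z_full is None or not np.isfinite(ll_full) or not np.isfinite(ll_null):
        return LDTestResult(
            theta_hat=float("nan"),
            statistic=0.0,
            p_value=1.0,
            s_hat=float("nan"),
            t_hat=float("nan"),
            converged=False,
        )
    stat = max(2.0 * (ll_full - ll_null), 0.0)
    return LDTestResult(
        theta_hat=float(np.exp(z_full[2])),
        statistic=stat,
        p_value=float(chi2.sf(stat, df=1)),
        s_hat=_expit(z_full[0]),
        t_hat=_expit(z_full[1]),
        converged=ok_full and ok_null,
    )


def lrt_genotype(counts: np.ndarray, theta_null_bound: float = 1.0) -> LDTestResult:
    """One-sided LRT for positive LD from a 3x3 genotype-combination table."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (3, 3) or np.any(c < 0):
        raise ValueError("counts must be a nonnegative 3x3 table")
    return lrt_summary(genotype_table_as_sets(c), theta_null_bound)


# ---------------------------------------------------------------------------
# gnomAD-style partitioning into independent sets


SUBSETS = ("controls", "non_cancer", "all")
SEXES = ("female", "male")


def _stratum_counts(
    per_stratum: Mapping[str, tuple[int, int, int | None]],
    subset: str,
    stratum: str,
    sex: str,
) -> tuple[int, int]:
    key = f"{subset}_{stratum}_{sex}" if subset != "all" else f"{stratum}_{sex}"
    if key not in per_stratum:
        raise KeyError(f"missing per-stratum count field {key!r}")
    ac, an, _ = per_stratum[key]
    return ac, an


def partition_six_sets(
    per_stratum_1: Mapping[str, tuple[int, int, int | None]],
    per_stratum_2: Mapping[str, tuple[int, int, int | None]],
    stratum: str,
) -> SixSetCounts:
    """Build the six independent pooled-count sets of a variant pair.

    gnomAD publishes nested subset counts: ``controls`` is a subset of
    ``non_cancer``, which is a subset of the full cohort.  Subtraction yields
    three *disjoint* subsets — controls, non-cancer-non-controls, cancer —
    and splitting each by sex gives six independent sets per ethnicity
    stratum.  The haplotype total of a set is the rounded average of the two
    variants' AN fields.
    """
    xs, ys, ns = [], [], []
    for sex in SEXES:
        prev_ac = {1: 0, 2: 0}
        prev_an = {1: 0, 2: 0}
        for subset in SUBSETS:
            ac1, an1 = _stratum_counts(per_stratum_1, subset, stratum, sex)
            ac2, an2 = _stratum_counts(per_stratum_2, subset, stratum, sex)
            dx, dy = ac1 - prev_ac[1], ac2 - prev_ac[2]
            dn1, dn2 = an1 - prev_an[1], an2 - prev_an[2]
            if min(dx, dy, dn1, dn2) < 0:
                raise ValueError(
                    f"negative count after subtracting nested subsets at "
                    f"{subset}_{stratum}_{sex}"
                )
            xs.append(dx)
            ys.append(dy)
            ns.append(int(round((dn1 + dn2) / 2.0)))
            prev_ac = {1: ac1, 2: ac2}
            prev_an = {1: an1, 2: an2}
    xs, ys, ns = np.array(xs), np.array(ys), np.array(ns)
    keep = ns > 0
    xs = np.minimum(xs, ns)
    ys = np.minimum(ys, ns)
    if not keep.any():
        raise ValueError("all partitioned sets are empty")
    return SixSetCounts(x=xs[keep], y=ys[keep], n=ns[keep])


# ---------------------------------------------------------------------------
# within-gene LD scan


@dataclass(frozen=True)
class LDScanVariant:
    """A qualified variant entering the within-gene LD scan."""

    key: str
    chrom: str
    pos: int
    counts: np.ndarray  # alternate allele count per independent set
    an: np.ndarray  # haplotype total per independent set
    af: float
    ac: int
    missingness: float = 0.0
    is_snv: bool = True


def scan_gene_pairs(
    genes: Mapping[str, Sequence[LDScanVariant]],
    stratum: str = "all",
    af_max: float = 0.01,
    ac_min: int = 10,
    missingness_max: float = 0.1,
    fdr_level: float = 0.05,
    theta_high: float = 150.0,
    p_store: float | None = None,
) -> list[LDPair]:
    """Test all within-gene variant pairs for positive LD.

    Variants are restricted to AF <= ``af_max``, AC >= ``ac_min`` and
    missingness <= ``missingness_max``.  Per gene, the haplotype total of each
    set is the rounded average over its qualified variants' AN.  FDR across
    the scan by Benjamini-Hochberg; pairs with estimated theta above
    ``theta_high`` are flagged high-LD.  ``p_store`` optionally drops pairs
    with larger P values from the returned store.
    """
    pairs: list[LDPair] = []
    pvals: list[float] = []
    for gene, variants in genes.items():
        qualified = [
            v
            for v in variants
            if v.af <= af_max and v.ac >= ac_min and v.missingness <= missingness_max
        ]
        if len(qualified) < 2:
            continue
        n_sets = np.round(
            np.mean(np.stack([v.an for v in qualified]), axis=0)
        ).astype(int)
        for a in range(len(qualified) - 1):
            for b in range(a + 1, len(qualified)):
                v1, v2 = qualified[a], qualified[b]
                data = SixSetCounts(
                    x=np.minimum(v1.counts, n_sets),
                    y=np.minimum(v2.counts, n_sets),
                    n=n_sets,
                )
                res = lrt_summary(data)
                if res.skipped:
                    continue
                dist = (
                    abs(v1.pos - v2.pos) if v1.chrom == v2.chrom else None
                )
                pairs.append(
                    LDPair(
                        key1=v1.key,
                        key2=v2.key,
                        stratum=stratum,
                        theta_hat=res.theta_hat,
                        statistic=res.statistic,
                        p_value=res.p_value,
                        distance_bp=dist,
                        high_ld=res.theta_hat > theta_high,
                    )
                )
                pvals.append(res.p_value)
    if not pairs:
        return []
    fdrs = bh_adjust(np.array(pvals))
    out = [replace(p, fdr=float(f)) for p, f in zip(pairs, fdrs)]
    if p_store is not None:
        out = [p for p in out if p.p_value < p_store]
    return out


def mnv_compare(
    ld_pairs: Iterable[LDPair],
    mnv_reference: Iterable[tuple[str, str]],
    max_distance: int = 2,
    theta_high: float = 150.0,
) -> dict[str, float]:
    """Overlap of detected high-LD nearby pairs with a reference MNV set.

    Restricts to pairs flagged high-LD (theta above ``theta_high``) with
    distance <= ``max_distance`` and reports how many appear in the reference
    (keys are unordered).
    """
    ref = {frozenset(p) for p in mnv_reference}
    candidates = [
        p
        for p in ld_pairs
        if p.high_ld
        and p.theta_hat > theta_high
        and p.distance_bp is not None
        and p.distance_bp <= max_distance
    ]
    n_hit = sum(1 for p in candidates if frozenset((p.key1, p.key2)) in ref)
    n = len(candidates)
    return {
        "n_detected": float(n),
        "n_in_reference": float(n_hit),
        "overlap_fraction": n_hit / n if n else 0.0,
    }
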