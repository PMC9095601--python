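"""Consistent case/control quality control and variant filtering.

Separately called cohorts must be filtered *consistently*: a variant kept in
one cohort but dropped in the other biases the carrier table.  The rules here
mirror that principle:

* coverage: a site is analyzable only if at least ``coverage_fraction`` of
  samples reach ``depth_threshold`` reads in *both* cohorts (defaults 90% at
  depth 10);
* status: a variant must PASS its cohort's QC filter in *both* cohorts, be
  absent from the blacklist, and have missingness <= ``max_missingness`` in
  both (missingness = 1 - AN / (2 * cohort size));
* allele frequency: filtering uses the *joint* AF pooled over cases and
  controls, AF = (AC_case + AC_control) / (AN_case + AN_control); for
  stratified analyses the maximum per-ethnicity joint AF is compared against
  the threshold, and optionally AF_popmax (the maximum reference-panel AF
  across ancestries) as well.

Every excluded variant carries exactly one primary exclusion reason; the
per-stage attrition log is part of the pipeline contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exact import ContingencyTable, fet_pvalue
from .io import CoverageTrack, VariantSummary

DEFAULT_COVERAGE_THRESHOLDS = (1, 5, 10, 15, 20, 25, 30, 50, 100)


@dataclass(frozen=True)
class CategoryRule:
    """A variant-category rule: consequence set plus an optional REVEL gate.

    ``score_gated`` lists the consequences within ``consequences`` whose
    inclusion additionally requires REVEL >= ``revel_min`` (upper bound rules
    use ``revel_max``).
    """

    name: str
    consequences: frozenset[str]
    score_gated: frozenset[str] = frozenset()
    revel_min: float | None = None
    revel_max: float | None = None


#: variants plausibly damaging: protein-truncating, or missense with high REVEL
PATHOGENIC_RULE = CategoryRule(
    name="pathogenic",
    consequences=frozenset(
        {"stopgain", "frameshift_insertion", "frameshift_deletion", "nonsynonymous"}
    ),
    score_gated=frozenset({"nonsynonymous"}),
    revel_min=0.65,
)

#: likely-neutral variants (ProxECAT-style denominator)
NONFUNCTIONAL_RULE = CategoryRule(
    name="nonfunctional",
    consequences=frozenset({"synonymous", "nonsynonymous"}),
    score_gated=frozenset({"nonsynonymous"}),
    revel_max=0.2,
)

SYNONYMOUS_RULE = CategoryRule(name="synonymous", consequences=frozenset({"synonymous"}))

BUILTIN_RULES = {
    r.name: r for r in (PATHOGENIC_RULE, NONFUNCTIONAL_RULE, SYNONYMOUS_RULE)
}


@dataclass
class QCConfig:
    depth_threshold: int = 10
    coverage_fraction: float = 0.9
    max_missingness: float = 0.1
    joint_af_threshold: float = 1e-3
    use_popmax: bool = False
    popmax_threshold: float = 1e-3
    category_rules: tuple[CategoryRule, ...] = (PATHOGENIC_RULE,)

    def __post_init__(self) -> None:
        for name in ("coverage_fraction", "max_missingness", "joint_af_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_threshold < 0:
            raise ValueError("depth_threshold must be nonnegative")


@dataclass(frozen=True)
class BlacklistEntry:
    key: str
    reason: str  # failed_gnomad_filter | wes_wgs_af_discrepancy | user


@dataclass
class FilterLog:
    """Primary exclusion reason per dropped variant, and per-stage attrition."""

    reasons: dict[str, str] = field(default_factory=dict)

    def exclude(self, key: str, reason: str) -> None:
        self.reasons.setdefault(key, reason)

    def attrition(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for reason in self.reasons.values():
            out[reason] = out.get(reason, 0) + 1
        return out


def coverage_summarize(
    depths: np.ndarray,
    positions: Sequence[tuple[str, int]],
    thresholds: Sequence[int] = DEFAULT_COVERAGE_THRESHOLDS,
) -> CoverageTrack:
    """Summarize a samples x positions depth matrix into a coverage track.

    For every position and depth threshold t, the fraction of samples with
    depth >= t; fractions are nonincreasing in t by construction.
    """
    depths = np.asarray(depths)
    if depths.ndim != 2 or depths.shape[0] == 0:
        raise ValueError("depth matrix must be 2-D with at least one sample")
    if depths.shape[1] != len(positions):
        raise ValueError("positions do not match depth matrix columns")
    if np.any(depths < 0):
        raise ValueError("depths must be nonnegative")
    thresholds = tuple(int(t) for t in thresholds)
    frac = (
        depths[:, :, None] >= np.asarray(thresholds)[None, None, :]
    ).mean(axis=0)
    return CoverageTrack(
        thresholds=thresholds,
        fractions={pos: frac[j] for j, pos in enumerate(positions)},
    )


def site_coverage_filter(
    case_cov: CoverageTrack,
    control_cov: CoverageTrack,
    cfg: QCConfig,
    positions: Iterable[tuple[str, int]] | None = None,
) -> set[tuple[str, int]]:
    """Positions adequately covered in BOTH cohorts.

    A position absent from either track counts as failing.
    """
    if positions is None:
        positions = set(case_cov.fractions) & set(control_cov.fractions)
    kept = set()
    for pos in positions:
        ok_case = (
            case_cov.fraction_at(pos[0], pos[1], cfg.depth_threshold)
            >= cfg.coverage_fraction
        )
        ok_ctrl = (
            control_cov.fraction_at(pos[0], pos[1], cfg.depth_threshold)
            >= cfg.coverage_fraction
        )
        if ok_case and ok_ctrl:
            kept.add(pos)
    return kept


def _missingness(vs: VariantSummary, cohort_size: int) -> float:
    if cohort_size <= 0:
        raise ValueError(f"unknown cohort size for missingness at {vs.key}")
    return 1.0 - vs.an / (2.0 * cohort_size)


def consistent_variant_filter(
    case_variants: Sequence[VariantSummary],
    control_variants: Sequence[VariantSummary],
    case_n: int,
    control_n: int,
    blacklist: Iterable[BlacklistEntry] = (),
    cfg: QCConfig | None = None,
    log: FilterLog | None = None,
) -> list[tuple[VariantSummary, VariantSummary]]:
    """Pairs of case/control records passing consistent QC in both cohorts.

    Retains variants present in both cohorts (a variant absent from one
    cohort's call set cannot be tested consistently; absent control variants
    may be re-added upstream as AC=0 records when the site is well covered),
    with PASS status on both sides, off the blacklist, and with missingness
    within bounds on both sides.  Symmetric in the two cohorts by
    construction.
    """
    cfg = cfg or QCConfig()
    log = log if log is not None else FilterLog()
    blacklisted = {b.key for b in blacklist}
    controls_by_key = {v.key: v for v in control_variants}
    kept: list[tuple[VariantSummary, VariantSummary]] = []
    for cv in case_variants:
        ctrl = controls_by_key.get(cv.key)
        if ctrl is None:
            log.exclude(cv.key, "absent_in_other_cohort")
            continue
        if cv.key in blacklisted:
            log.exclude(cv.key, "blacklist")
            continue
        if not (cv.passed and ctrl.passed):
            log.exclude(cv.key, "failed_filter_either_cohort")
            continue
        if (
            _missingness(cv, case_n) > cfg.max_missingness
            or _missingness(ctrl, control_n) > cfg.max_missingness
        ):
            log.exclude(cv.key, "missingness")
            continue
        kept.append((cv, ctrl))
    return kept


def joint_af(ac_case: int, an_case: int, ac_control: int, an_control: int) -> float:
    """Pooled case+control alternate allele frequency."""
    denom = an_case + an_control
    if denom <= 0:
        raise ValueError("joint AF undefined: AN_case + AN_control = 0")
    return (ac_case + ac_control) / denom


def stratified_max_joint_af(
    case_vs: VariantSummary,
    control_vs: VariantSummary,
    strata: Sequence[str],
) -> float:
    """Maximum per-ethnicity joint AF; strata with AN = 0 on both sides skip."""
    best = 0.0
    seen = False
    for label in strata:
        c_ac, c_an, _ = case_vs.per_stratum.get(label, (0, 0, None))
        g_ac, g_an, _ = control_vs.per_stratum.get(label, (0, 0, None))
        if c_an + g_an == 0:
            continue
        seen = True
        best = max(best, joint_af(c_ac, c_an, g_ac, g_an))
    if not seen:
        raise ValueError(
            f"no per-stratum counts available for {case_vs.key}; "
            "stratified AF filtering requires them"
        )
    return best


def af_filter(
    pairs: Sequence[tuple[VariantSummary, VariantSummary]],
    cfg: QCConfig,
    strata: Sequence[str] | None = None,
    log: FilterLog | None = None,
) -> list[tuple[VariantSummary, VariantSummary]]:
    """Keep variants whose (stratified max) joint AF is within the threshold.

    When ``cfg.use_popmax`` is set, the control-side AF_popmax annotation is
    additionally bounded by ``cfg.popmax_threshold``.
    """
    log = log if log is not None else FilterLog()
    kept = []
    for cv, gv in pairs:
        if strata:
            af = stratified_max_joint_af(cv, gv, strata)
        else:
            af = joint_af(cv.ac, cv.an, gv.ac, gv.an)
        if af > cfg.joint_af_threshold:
            log.exclude(cv.key, "joint_af")
            continue
        if cfg.use_popmax:
            popmax = gv.annotations.get("AF_popmax")
            if popmax is not None and float(popmax) > cfg.popmax_threshold:
                log.exclude(cv.key, "af_popmax")
                continue
        kept.append((cv, gv))
    return kept


def select_category(
    variants: Sequence[VariantSummary],
    rules: Sequence[CategoryRule],
    log: FilterLog | None = None,
) -> dict[str, list[VariantSummary]]:
    """Partition variants into the categories whose rules they match.

    A score-gated consequence with no REVEL annotation is excluded from that
    rule and logged.
    """
    log = log if log is not None else FilterLog()
    out: dict[str, list[VariantSummary]] = {r.name: [] for r in rules}
    for vs in variants:
        consequence = vs.annotations.get("consequence")
        revel = vs.annotations.get("REVEL")
        for rule in rules:
            if consequence not in rule.consequences:
                continue
            if consequence in rule.score_gated:
                if revel is None:
                    log.exclude(vs.key, f"missing_revel_for_{rule.name}")
                    continue
                r = float(revel)
                if rule.revel_min is not None and r < rule.revel_min:
                    continue
                if rule.revel_max is not None and r >= rule.revel_max:
                    continue
            out[rule.name].append(vs)
    return out


def exact_two_proportion_pvalue(ac1: int, an1: int, ac2: int, an2: int) -> float:
    """Two-sided exact test that two allele counts share one frequency."""
    t = ContingencyTable(x=ac1, m=an1, n=an2, k=ac1 + ac2)
    return fet_pvalue(t, "two_sided")


def build_blacklist(
    exome_variants: Sequence[VariantSummary],
    genome_variants: Sequence[VariantSummary],
    alpha: float = 1e-5,
    min_fold_change: float = 5.0,
) -> list[BlacklistEntry]:
    """Blacklist variants failing either platform or with discrepant AFs.

    A variant failing the QC filter on either sequencing platform is
    blacklisted outright.  For variants passing both, allele frequencies on
    the two platforms are compared with a two-sided exact two-proportion test;
    a discrepancy significant at ``alpha`` with fold change >=
    ``min_fold_change`` is blacklisted.  (The thresholds are conservative
    defaults with the stated intent, both configurable.)
    """
    genomes = {v.key: v for v in genome_variants}
    out: list[BlacklistEntry] = []
    for ev in exome_variants:
        gv = genomes.get(ev.key)
        if not ev.passed or (gv is not None and not gv.passed):
            out.append(BlacklistEntry(key=ev.key, reason="failed_gnomad_filter"))
            continue
        if gv is None or ev.an == 0 or gv.an == 0:
            continue
        p = exact_two_proportion_pvalue(ev.ac, ev.an, gv.ac, gv.an)
        af_e, af_g = ev.af, gv.af
        if min(af_e, af_g) == 0.0:
            fold = float("inf") if max(af_e, af_g) > 0 else 1.0
        else:
            fold = max(af_e, af_g) / min(af_e, af_g)
        if p < alpha and fold >= min_fold_change:
            out.append(BlacklistEntry(key=ev.key, reason="wes_wgs_af_discrepancy"))
    return out
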