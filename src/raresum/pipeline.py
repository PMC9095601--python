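"""Orchestration: QC -> carrier counting -> exact tests -> calibration/FDR.

``run_burden`` is the gene-prioritization entry point.  Cases may be a full
genotype matrix (carriers counted directly, with per-sample LD screening of
double-heterozygous carriers) or summary counts (carriers estimated like
controls).  Controls are always summary counts.  Analyses are either pooled
(Fisher's exact test) or ethnicity-stratified (exact CMH over the strata
present on both sides; samples labeled "other" are never used).

The gene universe is the set of genes with at least one qualified variant
after all filters; genes with zero carriers in cases and controls combined
have a degenerate (single-point) null and are excluded from testing and from
inflation-factor estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    LambdaEstimate,
    bh_adjust,
    discrete_stepdown_adjust,
    estimate_lambda_emp,
    expected_order_statistics,
    rbh_adjust,
    sample_null_pvalues,
)
from .counts import (
    MODELS,
    Model,
    case_counts_from_genotypes,
    expected_control_counts,
    genotype_freqs_from_counts,
    model_probabilities,
    prune_control_variants_for_ld,
)
from .exact import (
    ContingencyTable,
    PValueSupport,
    StratifiedTables,
    cmh_odds_ratio,
    cmh_pvalue,
    cmh_support,
    fet_support,
    odds_ratio,
)
from .io import GenotypeMatrix, VariantSummary
from .qc import (
    FilterLog,
    QCConfig,
    af_filter,
    consistent_variant_filter,
    select_category,
    site_coverage_filter,
)
from .exact import fet_pvalue

FDRMethod = Literal["BH", "RBH_P", "RBH_UL", "ADBH_SD"]


@dataclass
class RunConfig:
    qc: QCConfig = field(default_factory=QCConfig)
    models: tuple[Model, ...] = ("DOM",)
    stratified: bool = False
    strata: tuple[str, ...] = ()
    alternative: str = "two_sided"
    fdr_method: FDRMethod = "BH"
    n_null_replicates: int = 100
    seed: int = 0
    ld_p_threshold: float = 0.1
    ld_fdr_threshold: float = 0.05
    exome_wide_alpha: float = 2.5e-6

    def __post_init__(self) -> None:
        if self.stratified and not self.strata:
            raise ValueError("stratified analysis requires stratum labels")
        bad = set(self.models) - set(MODELS)
        if bad:
            raise ValueError(f"unknown models: {bad}")


@dataclass
class BurdenResult:
    results: pd.DataFrame
    lambdas: dict[Model, LambdaEstimate]
    qq_data: dict[Model, pd.DataFrame]
    filter_log: FilterLog
    config: RunConfig


def _stratum_counts_of(
    vs: VariantSummary, label: str | None
) -> tuple[int, int, int | None]:
    if label is None:
        return vs.ac, vs.an, vs.nhomalt
    if label not in vs.per_stratum:
        raise KeyError(f"variant {vs.key} lacks counts for stratum {label!r}")
    return vs.per_stratum[label]


def _control_carrier_estimates(
    controls: Sequence[VariantSummary],
    label: str | None,
    ld_prune_pairs: set[tuple[str, str]],
) -> dict[Model, tuple[int, int]]:
    """Estimated (n3, n4) per model for one gene in one stratum.

    The control cohort size is the rounded mean AN/2 over the gene's
    qualified variants.  For the recessive / double-het models, LD-linked
    variants are first pruned to the highest-AF representative.
    """
    triples = [_stratum_counts_of(v, label) for v in controls]
    ans = [an for _, an, _ in triples]
    n_controls = int(round(float(np.mean(ans)) / 2.0)) if ans else 0
    if n_controls <= 0:
        return {m: (0, 0) for m in MODELS}
    freqs = []
    for (ac, an, nhom) in triples:
        if an <= 0:
            continue
        freqs.append(genotype_freqs_from_counts(ac, an, nhom))
    if not freqs:
        return {m: (0, n_controls) for m in MODELS}
    probs_all = model_probabilities(freqs)
    out = expected_control_counts(probs_all, n_controls)
    if ld_prune_pairs:
        afs = {}
        by_key = {}
        for v, (ac, an, nhom) in zip(controls, triples):
            if an > 0:
                afs[v.key] = ac / an
                by_key[v.key] = (ac, an, nhom)
        kept = prune_control_variants_for_ld(afs, ld_prune_pairs)
        pruned_freqs = [
            genotype_freqs_from_counts(*by_key[k]) for k in sorted(kept)
        ]
        if pruned_freqs:
            probs_pruned = model_probabilities(pruned_freqs)
            pruned = expected_control_counts(probs_pruned, n_controls)
            out = {"DOM": out["DOM"], "REC": pruned["REC"], "2HET": pruned["2HET"]}
    return out


def _case_counts(
    cases: GenotypeMatrix | Sequence[VariantSummary],
    gene_variant_keys: Sequence[str],
    label: str | None,
    ld_pair_pvalues: Mapping[tuple[str, str], float],
    ld_p_threshold: float,
    key_to_col: Mapping[str, int] | None = None,
    stratum_rows: Mapping[str | None, np.ndarray] | None = None,
) -> tuple[dict[Model, int], int]:
    """(qualifying case counts per model, case cohort size) for one gene/stratum."""
    if isinstance(cases, GenotypeMatrix):
        if key_to_col is None:
            key_to_col = {v.key: j for j, v in enumerate(cases.variants)}
        cols = [key_to_col[k] for k in gene_variant_keys if k in key_to_col]
        if stratum_rows is not None and label in stratum_rows:
            rows = stratum_rows[label]
        else:
            rows = (
                cases.sample_indices([label]) if label else cases.sample_indices()
            )
        sub = cases.genotypes[np.ix_(rows, cols)]
        sub = np.where(sub < 0, 0, sub)
        col_pairs = {}
        for a in range(len(cols)):
            for b in range(a + 1, len(cols)):
                pair_key = tuple(
                    sorted((gene_variant_keys[a], gene_variant_keys[b]))
                )
                if pair_key in ld_pair_pvalues:
                    col_pairs[(a, b)] = ld_pair_pvalues[pair_key]
        counts = case_counts_from_genotypes(
            sub, col_pairs, ld_p_threshold=ld_p_threshold
        )
        return counts, len(rows)
    # summary-count cases: estimate exactly like controls
    by_key = {v.key: v for v in cases}
    triples = [
        _stratum_counts_of(by_key[k], label)
        for k in gene_variant_keys
        if k in by_key
    ]
    ans = [an for _, an, _ in triples if an > 0]
    n_cases = int(round(float(np.mean(ans)) / 2.0)) if ans else 0
    freqs = [
        genotype_freqs_from_counts(ac, an, nhom)
        for (ac, an, nhom) in triples
        if an > 0
    ]
    if not freqs or n_cases == 0:
        return {m: 0 for m in MODELS}, n_cases
    probs = model_probabilities(freqs)
    est = expected_control_counts(probs, n_cases)
    return {m: est[m][0] for m in MODELS}, n_cases


def qualified_variants(
    case_summaries: Sequence[VariantSummary],
    control_summaries: Sequence[VariantSummary],
    case_n: int,
    control_n: int,
    cfg: RunConfig,
    case_coverage=None,
    control_coverage=None,
    blacklist=(),
    log: FilterLog | None = None,
) -> list[tuple[VariantSummary, VariantSummary]]:
    """Apply the full QC/filter cascade and return qualified case/control pairs.

    Order: coverage, PASS/blacklist/missingness, joint-AF (so the log can
    attribute losses per stage), then category selection.
    """
    log = log if log is not None else FilterLog()
    if case_coverage is not None and control_coverage is not None:
        positions = {(v.chrom, v.pos) for v in case_summaries}
        covered = site_coverage_filter(
            case_coverage, control_coverage, cfg.qc, positions
        )
        retained = []
        for v in case_summaries:
            if (v.chrom, v.pos) in covered:
                retained.append(v)
            else:
                log.exclude(v.key, "coverage")
        case_summaries = retained
    pairs = consistent_variant_filter(
        case_summaries,
        control_summaries,
        case_n,
        control_n,
        blacklist=blacklist,
        cfg=cfg.qc,
        log=log,
    )
    pairs = af_filter(
        pairs, cfg.qc, strata=cfg.strata if cfg.stratified else None, log=log
    )
    if cfg.qc.category_rules:
        selected = select_category(
            [cv for cv, _ in pairs], cfg.qc.category_rules, log=log
        )
        chosen = {v.key for vs in selected.values() for v in vs}
        pairs = [p for p in pairs if p[0].key in chosen]
    return pairs


def run_burden(
    cases: GenotypeMatrix | Sequence[VariantSummary],
    control_summaries: Sequence[VariantSummary],
    cfg: RunConfig,
    case_n: int | None = None,
    case_coverage=None,
    control_coverage=None,
    blacklist=(),
    ld_pairs: pd.DataFrame | None = None,
) -> BurdenResult:
    """Gene-level burden test of cases against summary-count controls.

    Returns per gene x model carrier tables, exact P values, conditional-MLE
    odds ratios, adjusted P values, the run's inflation factors, and QQ data.
    Deterministic given ``cfg.seed``.
    """
    log = FilterLog()
    if isinstance(cases, GenotypeMatrix):
        case_summaries = _summaries_from_matrix(cases, cfg)
        case_n_eff = len(cases.samples)
    else:
        case_summaries = list(cases)
        if case_n is None:
            raise ValueError("case_n is required for summary-count cases")
        case_n_eff = case_n
    control_n = (
        int(round(max(v.an for v in control_summaries) / 2.0))
        if control_summaries
        else 0
    )
    pairs = qualified_variants(
        case_summaries,
        control_summaries,
        case_n_eff,
        control_n,
        cfg,
        case_coverage,
        control_coverage,
        blacklist,
        log,
    )
    genes: dict[str, list[tuple[VariantSummary, VariantSummary]]] = {}
    for cv, gv in pairs:
        gene = cv.annotations.get("gene") or gv.annotations.get("gene")
        if gene is None:
            log.exclude(cv.key, "no_gene_annotation")
            continue
        genes.setdefault(str(gene), []).append((cv, gv))
    if not genes:
        empty = pd.DataFrame(
            columns=["gene", "model", "stratum", "n1", "n2", "n3", "n4",
                     "p_value", "odds_ratio", "p_adjusted", "variants"]
        )
        return BurdenResult(empty, {}, {}, log, cfg)

    ld_p_lookup: dict[tuple[str, str], float] = {}
    ld_prune_pairs: set[tuple[str, str]] = set()
    if ld_pairs is not None and len(ld_pairs):
        for row in ld_pairs.itertuples(index=False):
            key = tuple(sorted((row.key1, row.key2)))
            ld_p_lookup[key] = min(
                float(row.p_value), ld_p_lookup.get(key, 1.0)
            )
            if float(row.fdr) < cfg.ld_fdr_threshold:
                ld_prune_pairs.add(key)

    strata: Sequence[str | None]
    if cfg.stratified:
        strata = [s for s in cfg.strata if s != "other"]
    else:
        strata = [None]

    key_to_col = (
        {v.key: j for j, v in enumerate(cases.variants)}
        if isinstance(cases, GenotypeMatrix)
        else None
    )
    stratum_rows = (
        {label: cases.sample_indices([label] if label else None) for label in strata}
        if isinstance(cases, GenotypeMatrix)
        else None
    )
    rows = []
    supports: dict[Model, list[PValueSupport]] = {m: [] for m in cfg.models}
    tested_genes: dict[Model, list[str]] = {m: [] for m in cfg.models}
    observed: dict[Model, list[float]] = {m: [] for m in cfg.models}
    for gene in sorted(genes):
        gene_pairs = genes[gene]
        keys = [cv.key for cv, _ in gene_pairs]
        per_stratum_tables: dict[Model, list[ContingencyTable]] = {
            m: [] for m in cfg.models
        }
        detail = []
        for label in strata:
            case_counts, m_cases = _case_counts(
                cases if isinstance(cases, GenotypeMatrix) else case_summaries,
                keys,
                label,
                ld_p_lookup,
                cfg.ld_p_threshold,
                key_to_col=key_to_col,
                stratum_rows=stratum_rows,
            )
            ctrl_est = _control_carrier_estimates(
                [gv for _, gv in gene_pairs], label, ld_prune_pairs
            )
            for model in cfg.models:
                n1 = min(case_counts[model], m_cases)
                n3, n4 = ctrl_est[model]
                n_ctrl = n3 + n4
                if m_cases == 0 and n_ctrl == 0:
                    continue
                per_stratum_tables[model].append(
                    ContingencyTable(
                        x=n1, m=m_cases, n=n_ctrl, k=n1 + n3
                    )
                )
            detail.append((label, case_counts, m_cases, ctrl_est))
        for model in cfg.models:
            tables = [t for t in per_stratum_tables[model] if t.m + t.n > 0]
            if not tables:
                continue
            k_total = sum(t.k for t in tables)
            if k_total == 0:
                # no carriers anywhere: degenerate null, excluded by contract
                continue
            if len(tables) == 1:
                t = tables[0]
                support = fet_support(t.m, t.n, t.k, cfg.alternative)
                p = support.pvalue_of(t.x)
                or_est = odds_ratio(t)
            else:
                st = StratifiedTables(tuple(tables))
                support = cmh_support(st, cfg.alternative)
                p = support.pvalue_of(st.statistic)
                or_est = cmh_odds_ratio(st)
            supports[model].append(support)
            tested_genes[model].append(gene)
            observed[model].append(p)
            rows.append(
                {
                    "gene": gene,
                    "model": model,
                    "stratum": "combined" if len(tables) > 1 else (strata[0] or "all"),
                    "n1": sum(t.x for t in tables),
                    "n2": sum(t.m - t.x for t in tables),
                    "n3": sum(t.k - t.x for t in tables),
                    "n4": sum(t.n - t.k + t.x for t in tables),
                    "p_value": p,
                    "odds_ratio": or_est,
                    "variants": ",".join(keys),
                }
            )
    results = pd.DataFrame(rows)
    lambdas: dict[Model, LambdaEstimate] = {}
    qq: dict[Model, pd.DataFrame] = {}
    if len(results):
        adjusted = np.full(len(results), np.nan)
        rng = np.random.default_rng(cfg.seed)
        for model in cfg.models:
            obs = np.array(observed[model])
            if len(obs) == 0:
                continue
            npm = sample_null_pvalues(
                supports[model], cfg.n_null_replicates, rng
            )
            expected = expected_order_statistics(npm)
            try:
                lambdas[model] = estimate_lambda_emp(obs, expected)
            except ValueError:
                pass
            qq[model] = pd.DataFrame(
                {
                    "rank": np.arange(1, len(obs) + 1),
                    "expected": expected,
                    "observed": np.sort(obs),
                }
            )
            if cfg.fdr_method == "BH":
                adj = bh_adjust(obs)
            elif cfg.fdr_method == "RBH_P":
                adj = rbh_adjust(obs, npm, variant="P")
            elif cfg.fdr_method == "RBH_UL":
                adj = rbh_adjust(obs, npm, variant="UL")
            elif cfg.fdr_method == "ADBH_SD":
                adj = discrete_stepdown_adjust(obs, supports[model])
            else:
                raise ValueError(f"unknown FDR method {cfg.fdr_method!r}")
            mask = results["model"] == model
            idx = results.index[mask]
            gene_order = {g: i for i, g in enumerate(tested_genes[model])}
            adjusted[idx] = adj[[gene_order[g] for g in results.loc[idx, "gene"]]]
        results["p_adjusted"] = adjusted
        results = results.sort_values(
            ["model", "p_value", "gene"], kind="stable"
        ).reset_index(drop=True)
    return BurdenResult(results, lambdas, qq, log, cfg)


def _summaries_from_matrix(
    gm: GenotypeMatrix, cfg: RunConfig
) -> list[VariantSummary]:
    """Case-side summary records (pooled and per-stratum) from genotypes."""
    from .io import genotype_summary_stats

    labels = np.array([gm.ethnicity.get(s, "other") for s in gm.samples])
    ac, an, nhom = genotype_summary_stats(gm.genotypes)
    per_label = {
        label: genotype_summary_stats(gm.genotypes[labels == label])
        for label in sorted(set(labels))
    }
    return [
        VariantSummary(
            chrom=vs.chrom,
            pos=vs.pos,
            ref=vs.ref,
            alt=vs.alt,
            ac=int(ac[j]),
            an=int(an[j]),
            nhomalt=int(nhom[j]),
            filter_status=vs.filter_status,
            per_stratum={
                label: (int(sa[j]), int(sn[j]), int(sh[j]))
                for label, (sa, sn, sh) in per_label.items()
            },
            annotations=dict(vs.annotations),
        )
        for j, vs in enumerate(gm.variants)
    ]


def proxecat_test(
    functional_case_alleles: int,
    nonfunctional_case_alleles: int,
    functional_control_alleles: int,
    nonfunctional_control_alleles: int,
) -> float:
    """Pooled functional vs non-functional allele-count enrichment test.

    Forms the 2x2 table of functional/non-functional allele counts in cases
    and controls and applies the two-sided Fisher's exact test (replacing the
    original likelihood-ratio version, which is inaccurate at small counts).
    All-zero tables return P = 1.
    """
    a, b = functional_case_alleles, nonfunctional_case_alleles
    c, d = functional_control_alleles, nonfunctional_control_alleles
    if min(a, b, c, d) < 0:
        raise ValueError("allele counts must be nonnegative")
    if a + b + c + d == 0:
        return 1.0
    t = ContingencyTable(x=a, m=a + b, n=c + d, k=a + c)
    return fet_pvalue(t, "two_sided")
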