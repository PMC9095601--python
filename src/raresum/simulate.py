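"""Synthetic cohort generation for every stage of the framework.

The generators emulate the study design the framework targets: a modest case
cohort with full genotypes, a large control cohort observed only through
per-variant summary counts (aggregated from a latent simulated control
genotype matrix, so ground-truth model counts are known), per-position
coverage summaries, functional annotations driving category selection, and
optional planted signals — risk genes with a chosen carrier odds ratio, and
variant pairs in linkage disequilibrium with a chosen haplotype odds ratio.

Genotypes are drawn under Hardy-Weinberg equilibrium at allele frequencies
log-uniform on a rare-variant range (defaults 1e-5 .. 1e-3).  Every generator
is reproducible from its seed, and each dataset ships a truth table so
downstream checks never re-derive ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exact import fet_support, PValueSupport
from .io import (
    CoverageTrack,
    GenotypeMatrix,
    VariantSummary,
    genotype_summary_stats,
)
from .ld import HaplotypeModel, SixSetCounts
from .qc import DEFAULT_COVERAGE_THRESHOLDS

STRATA = ("nfe", "afr", "amr", "eas", "sas", "fin")


@dataclass
class SimSpec:
    """Study conditions for a synthetic case/control cohort."""

    n_genes: int = 200
    variants_per_gene: int = 5
    af_range: tuple[float, float] = (1e-5, 1e-3)
    n_cases: Mapping[str, int] = field(default_factory=lambda: {"nfe": 500})
    n_controls: Mapping[str, int] = field(default_factory=lambda: {"nfe": 10000})
    risk_genes: Mapping[str, float] = field(default_factory=dict)  # gene -> carrier OR
    #: allele frequency assigned to a planted risk gene's variants: each
    #: variant individually rare — an order of magnitude under typical
    #: joint-AF thresholds, so the filters keep it even after case
    #: enrichment — while the gene's combined carrier frequency lands at a
    #: few per thousand, the scale of an established predisposition gene
    risk_gene_af: float = 2.5e-4
    ld_pairs: Mapping[str, float] = field(default_factory=dict)  # gene -> theta
    missingness: float = 0.0
    coverage_fraction: float = 0.97
    fraction_synonymous: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missingness", "coverage_fraction", "fraction_synonymous"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SimulatedCohort:
    """In-memory synthetic dataset plus ground truth."""

    spec: SimSpec
    cases: GenotypeMatrix
    control_summaries: list[VariantSummary]
    control_genotypes: np.ndarray  # latent truth, samples x variants
    control_strata: np.ndarray  # stratum label per control sample
    case_coverage: CoverageTrack
    control_coverage: CoverageTrack
    truth: pd.DataFrame

    @property
    def case_summaries(self) -> list[VariantSummary]:
        """The case cohort reduced to summary counts (per stratum included)."""
        out = []
        strata = np.array(
            [self.cases.ethnicity[s] for s in self.cases.samples]
        )
        for j, vs in enumerate(self.cases.variants):
            col = self.cases.genotypes[:, j]
            per_stratum = {}
            for label in sorted(set(strata)):
                sub = col[strata == label]
                called = sub[sub >= 0]
                per_stratum[label] = (
                    int(called.sum()),
                    2 * len(called),
                    int((called == 2).sum()),
                )
            called = col[col >= 0]
            out.append(
                VariantSummary(
                    chrom=vs.chrom,
                    pos=vs.pos,
                    ref=vs.ref,
                    alt=vs.alt,
                    ac=int(called.sum()),
                    an=2 * len(called),
                    nhomalt=int((called == 2).sum()),
                    filter_status=vs.filter_status,
                    per_stratum=per_stratum,
                    annotations=dict(vs.annotations),
                )
            )
        return out


def _draw_afs(rng: np.random.Generator, n: int, af_range: tuple[float, float]) -> np.ndarray:
    lo, hi = np.log(af_range[0]), np.log(af_range[1])
    return np.exp(rng.uniform(lo, hi, size=n))


def _hwe_genotypes(
    rng: np.random.Generator, af: np.ndarray, n_samples: int
) -> np.ndarray:
    """Sample genotypes under HWE, sparsely.

    Draws per-variant heterozygote and homozygote counts from their binomial
    marginals and scatters them over distinct samples — distributionally
    identical to per-sample Binomial(2, af) draws but linear in the number of
    carriers, which for rare variants is orders of magnitude cheaper.
    """
    g = np.zeros((n_samples, len(af)), dtype=np.int8)
    p_hom = af * af
    p_het = 2.0 * af * (1.0 - af)
    k_hom = rng.binomial(n_samples, p_hom)
    # trinomial joint: het count conditional on the hom draw
    k_het = rng.binomial(n_samples - k_hom, p_het / (1.0 - p_hom))
    for j in np.flatnonzero(k_het + k_hom):
        k = int(k_het[j] + k_hom[j])
        if k * k > n_samples // 4:
            idx = rng.choice(n_samples, size=k, replace=False)
        else:
            idx = rng.integers(0, n_samples, size=k)
            while len(np.unique(idx)) < k:  # collisions are rare for k << n
                idx = rng.integers(0, n_samples, size=k)
        g[idx[: k_het[j]], j] = 1
        g[idx[k_het[j] :], j] = 2
    return g


_summary_stats = genotype_summary_stats


def simulate_cohort(spec: SimSpec) -> SimulatedCohort:
    """Generate a full case/control dataset with known ground truth.

    Control summary counts are aggregated from a latent control genotype
    matrix rather than sampled directly, so the true qualifying-sample counts
    under each model are known exactly.  In a planted risk gene the case
    carrier probability is inflated to the target carrier odds ratio; the
    extra carriers receive one heterozygous qualifying variant each.  In a
    planted LD gene the first two variants are drawn from the four-haplotype
    distribution at the requested theta instead of independently.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    m = spec.variants_per_gene
    n_var = spec.n_genes * m
    afs = _draw_afs(rng, n_var, spec.af_range)

    variants: list[VariantSummary] = []
    gene_of: list[str] = []
    pos0 = 1000
    for gi, gene in enumerate(genes):
        for vi in range(m):
            pos = pos0 + gi * 10_000 + vi * 100
            consequence = (
                "synonymous"
                if rng.random() < spec.fraction_synonymous
                else ("stopgain" if rng.random() < 0.3 else "nonsynonymous")
            )
            ann = {"gene": gene, "consequence": consequence}
            if consequence == "nonsynonymous":
                ann["REVEL"] = round(float(rng.uniform(0.65, 1.0)), 3)
            variants.append(
                VariantSummary(
                    chrom="1",
                    pos=pos,
                    ref="A",
                    alt="G",
                    ac=0,
                    an=0,
                    nhomalt=0,
                    annotations=ann,
                )
            )
            gene_of.append(gene)
    gene_of_arr = np.array(gene_of)

    # --- latent genotypes -------------------------------------------------
    for gene in spec.risk_genes:
        gi = genes.index(gene)
        afs[gi * m : (gi + 1) * m] = spec.risk_gene_af

    case_labels = [
        label for label, n in spec.n_cases.items() for _ in range(n)
    ]
    n_cases = len(case_labels)
    control_labels = np.array(
        [label for label, n in spec.n_controls.items() for _ in range(n)]
    )
    n_controls = len(control_labels)
    case_gt = _hwe_genotypes(rng, afs, n_cases)
    control_gt = _hwe_genotypes(rng, afs, n_controls)

    for gene, theta in spec.ld_pairs.items():
        gi = genes.index(gene)
        j1, j2 = gi * m, gi * m + 1
        s, t = float(afs[j1]), float(afs[j2])
        model = HaplotypeModel.from_marginals(s, t, theta)
        probs = [model.p11, model.p10, model.p01, model.p00]
        for gt, n_s in ((case_gt, n_cases), (control_gt, n_controls)):
            h1 = rng.choice(4, size=n_s, p=probs)
            h2 = rng.choice(4, size=n_s, p=probs)
            gt[:, j1] = (h1 <= 1).astype(np.int8) + (h2 <= 1).astype(np.int8)
            gt[:, j2] = np.isin(h1, (0, 2)).astype(np.int8) + np.isin(
                h2, (0, 2)
            ).astype(np.int8)

    for gene, odds_ratio in spec.risk_genes.items():
        gi = genes.index(gene)
        cols = slice(gi * m, (gi + 1) * m)
        gene_afs = afs[cols]
        q0 = 1.0 - float(np.prod((1.0 - gene_afs) ** 2))  # baseline carrier prob
        odds = odds_ratio * q0 / (1.0 - q0)
        q1 = odds / (1.0 + odds)
        if not 0.0 < q1 <= 0.9:
            # the generator refuses effects that saturate the case cohort:
            # they are outside the rare-variant design it emulates
            raise ValueError(
                f"carrier OR {odds_ratio} infeasible at baseline carrier "
                f"probability {q0:.3g} (implied case probability {q1:.3g})"
            )
        carrier = rng.random(n_cases) < q1
        case_gt[:, cols] = 0
        which = rng.integers(0, m, size=n_cases)
        for smp in np.flatnonzero(carrier):
            case_gt[smp, gi * m + which[smp]] = 1

    # --- missingness ------------------------------------------------------
    if spec.missingness > 0:
        mask = rng.random(case_gt.shape) < spec.missingness
        case_gt = np.where(mask, np.int8(-1), case_gt)
        ctrl_missing = rng.random(control_gt.shape) < spec.missingness
    else:
        ctrl_missing = np.zeros(control_gt.shape, dtype=bool)

    # --- case matrix as VariantSummary-backed GenotypeMatrix ---------------
    c_ac, c_an, c_nhom = _summary_stats(case_gt)
    case_variants = [
        VariantSummary(
            chrom=vs.chrom,
            pos=vs.pos,
            ref=vs.ref,
            alt=vs.alt,
            ac=int(c_ac[j]),
            an=int(c_an[j]),
            nhomalt=int(c_nhom[j]),
            annotations=dict(vs.annotations),
        )
        for j, vs in enumerate(variants)
    ]
    sample_names = [f"S{i:05d}" for i in range(n_cases)]
    cases = GenotypeMatrix(
        samples=sample_names,
        variants=case_variants,
        genotypes=case_gt,
        ethnicity=dict(zip(sample_names, case_labels)),
    )

    # --- control summaries (aggregation = ground truth conservation) -------
    observed_ctrl = (
        np.where(ctrl_missing, np.int8(-1), control_gt)
        if spec.missingness > 0
        else control_gt
    )
    g_ac, g_an, g_nhom = _summary_stats(observed_ctrl)
    ctrl_labels_distinct = sorted(set(control_labels))
    if len(ctrl_labels_distinct) == 1:
        stratum_stats = {ctrl_labels_distinct[0]: (g_ac, g_an, g_nhom)}
    else:
        stratum_stats = {
            label: _summary_stats(observed_ctrl[control_labels == label])
            for label in ctrl_labels_distinct
        }
    control_summaries = [
        VariantSummary(
            chrom=vs.chrom,
            pos=vs.pos,
            ref=vs.ref,
            alt=vs.alt,
            ac=int(g_ac[j]),
            an=int(g_an[j]),
            nhomalt=int(g_nhom[j]),
            per_stratum={
                label: (int(sa[j]), int(sn[j]), int(sh[j]))
                for label, (sa, sn, sh) in stratum_stats.items()
            },
            annotations=dict(vs.annotations),
        )
        for j, vs in enumerate(variants)
    ]

    # --- coverage ---------------------------------------------------------
    positions = [(v.chrom, v.pos) for v in variants]
    thresholds = DEFAULT_COVERAGE_THRESHOLDS
    t10 = thresholds.index(10)
    frac = spec.coverage_fraction
    arr = np.clip(frac + 0.03 - 0.002 * np.arange(len(thresholds)), 0.0, 1.0)
    arr[t10:] = np.minimum(arr[t10:], frac)
    arr.setflags(write=False)  # one shared profile for every simulated site
    case_cov = CoverageTrack(
        thresholds=thresholds, fractions={pos: arr for pos in positions}
    )
    control_cov = CoverageTrack(
        thresholds=thresholds, fractions={pos: arr for pos in positions}
    )

    # --- truth table --------------------------------------------------------
    # sparse per-(sample, gene) aggregation over the carrier entries only
    def _gene_carrier_counts(gt: np.ndarray) -> dict[str, np.ndarray]:
        rows, cols = np.nonzero(gt > 0)
        vals = gt[rows, cols].astype(np.int64)
        key = rows.astype(np.int64) * spec.n_genes + cols // m
        uk, inv = np.unique(key, return_inverse=True)
        totals = np.bincount(inv, weights=vals)
        hits = np.bincount(inv)
        gene_idx = (uk % spec.n_genes).astype(int)
        return {
            "dom": np.bincount(gene_idx, minlength=spec.n_genes),
            "rec": np.bincount(
                gene_idx[totals >= 2], minlength=spec.n_genes
            ),
            "het2": np.bincount(gene_idx[hits >= 2], minlength=spec.n_genes),
        }

    ctrl_counts = _gene_carrier_counts(control_gt)
    case_counts = _gene_carrier_counts(case_gt)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "is_risk": [g in spec.risk_genes for g in genes],
            "carrier_or": [spec.risk_genes.get(g, 1.0) for g in genes],
            "ld_theta": [spec.ld_pairs.get(g, 1.0) for g in genes],
            "true_control_dom": ctrl_counts["dom"],
            "true_control_rec": ctrl_counts["rec"],
            "true_control_2het": ctrl_counts["het2"],
            "true_case_dom": case_counts["dom"],
        }
    )

    return SimulatedCohort(
        spec=spec,
        cases=cases,
        control_summaries=control_summaries,
        control_genotypes=control_gt,
        control_strata=control_labels,
        case_coverage=case_cov,
        control_coverage=control_cov,
        truth=truth,
    )


def simulate_ld_sets(
    s: float,
    t: float,
    theta: float,
    n_list: Sequence[int],
    seed: int | np.random.Generator = 0,
) -> SixSetCounts:
    """Draw independent pooled-count sets for a variant pair at LD ``theta``."""
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    model = HaplotypeModel.from_marginals(s, t, theta)
    probs = np.array([model.p11, model.p10, model.p01, model.p00])
    n_arr = np.asarray(n_list, dtype=int)
    h = rng.multinomial(n_arr, np.tile(probs, (len(n_arr), 1)))
    return SixSetCounts(x=h[:, 0] + h[:, 1], y=h[:, 0] + h[:, 2], n=n_arr)


def simulate_null_supports(
    n_genes: int,
    n_cases: int = 336,
    n_controls: int = 125_748,
    k_max: int = 20,
    seed: int | np.random.Generator = 0,
    alternative: str = "two_sided",
) -> tuple[list[PValueSupport], np.ndarray, pd.DataFrame]:
    """Heterogeneous-margin null genes with exact supports and observed P values.

    Per gene the carrier total k is drawn uniformly on 0..k_max, the observed
    case-carrier count x from the central hypergeometric (no association), and
    the P value read off the gene's own support.  Returns (supports, observed
    P values, margins table).
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    supports: list[PValueSupport] = []
    observed = np.empty(n_genes)
    ks = rng.integers(0, k_max + 1, size=n_genes)
    rows = []
    for g in range(n_genes):
        k = int(ks[g])
        sup = fet_support(n_cases, n_controls, k, alternative)
        x = int(
            rng.hypergeometric(n_cases, n_controls, k) if k > 0 else 0
        )
        supports.append(sup)
        observed[g] = sup.pvalue_of(x)
        rows.append({"gene": g, "m": n_cases, "n": n_controls, "k": k, "x": x})
    return supports, observed, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plain-text VCF writers so the file-based pipeline can be exercised


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Total allele number">
##INFO=<ID=nhomalt,Number=A,Type=Integer,Description="Homozygous-alternate genotype count">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">
##INFO=<ID=REVEL,Number=1,Type=Float,Description="REVEL missense pathogenicity score">
##INFO=<ID=AF_popmax,Number=1,Type=Float,Description="Maximum ancestry-specific allele frequency">
"""


def _annotation_info(vs: VariantSummary) -> list[str]:
    out = []
    ann = vs.annotations
    if ann.get("gene") is not None:
        out.append(f"GENE={ann['gene']}")
    if ann.get("consequence") is not None:
        out.append(f"CSQ={ann['consequence']}")
    if ann.get("REVEL") is not None:
        out.append(f"REVEL={ann['REVEL']}")
    if ann.get("AF_popmax") is not None:
        out.append(f"AF_popmax={ann['AF_popmax']}")
    return out


def write_summary_vcf(
    variants: Sequence[VariantSummary], path: str | Path, strata: Sequence[str] = ()
) -> None:
    """Write summary-count records as an uncompressed gnomAD-style VCF."""
    lines = [_VCF_HEADER.rstrip("\n")]
    lines.append('##contig=<ID=1>')
    for label in strata:
        for f, num in (("AC", "A"), ("AN", "1"), ("nhomalt", "A")):
            lines.append(
                f'##INFO=<ID={f}_{label},Number={num},Type=Integer,'
                f'Description="{f} in {label}">'
            )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
        info = [f"AC={v.ac}", f"AN={v.an}"]
        if v.nhomalt is not None:
            info.append(f"nhomalt={v.nhomalt}")
        info.extend(_annotation_info(v))
        for label in strata:
            ac, an, nhom = v.per_stratum.get(label, (0, 0, 0))
            info.append(f"AC_{label}={ac}")
            info.append(f"AN_{label}={an}")
            if nhom is not None:
                info.append(f"nhomalt_{label}={nhom}")
        filt = v.filter_status if v.filter_status != "PASS" else "PASS"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{filt}\t{';'.join(info)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_case_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix as an uncompressed multi-sample VCF."""
    lines = [_VCF_HEADER.rstrip("\n"), '##contig=<ID=1>']
    lines.append(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.samples)
    )
    idx = sorted(range(len(gm.variants)), key=lambda j: (gm.variants[j].chrom, gm.variants[j].pos, gm.variants[j].alt))
    for j in idx:
        v = gm.variants[j]
        col = gm.genotypes[:, j]
        gts = ["./." if g < 0 else ("0/0", "0/1", "1/1")[g] for g in col]
        info = ";".join(
            [f"AC={v.ac}", f"AN={v.an}", f"nhomalt={v.nhomalt or 0}"]
            + _annotation_info(v)
        )
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{v.filter_status}\t"
            f"{info}\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")
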