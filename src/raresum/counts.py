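"""Carrier counting under dominant / recessive / double-heterozygous models.

For cases with full genotypes the qualifying samples are counted directly:
a sample qualifies under the dominant model when its summed alternate allele
count over a gene's qualified variants is >= 1, under the recessive model when
it is >= 2, and under the double-heterozygous model when at least two distinct
variants carry an alternate allele.  The double-heterozygous model is a subset
of the recessive model; without phasing it may include two variants on the
same haplotype.

For summary-count controls the qualifying sample counts must be *estimated*
from per-variant genotype frequencies, assuming independence between the rare
variants: with p_i0, p_i1, p_i2 the genotype frequencies of variant i,

    p_DOM  = 1 - prod_i p_i0
    p_2HET = sum_{i<j} (1 - p_i0)(1 - p_j0) * prod_{k != i,j} p_k0
    p_REC  = sum_i p_i2 * prod_{j != i} p_j0 + p_2HET

(the recessive/double-het expressions keep only the dominant-order terms:
three or more simultaneously carried rare variants are vanishingly unlikely).
Expected control counts are the probabilities scaled by the number of
controls.  Variant pairs in linkage disequilibrium violate the independence
assumption; the LD-aware corrections (pruning on the control side, per-sample
screening on the case side) are at the bottom of the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

Model = Literal["DOM", "REC", "2HET"]
MODELS: tuple[Model, ...] = ("DOM", "REC", "2HET")


@dataclass(frozen=True)
class GenotypeFrequencies:
    """Genotype frequencies (0/1/2 alternate alleles) of one variant."""

    p0: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        if min(self.p0, self.p1, self.p2) < -1e-9:
            raise ValueError(f"negative genotype frequency: {self}")
        if abs(self.p0 + self.p1 + self.p2 - 1.0) > 1e-9:
            raise ValueError(f"genotype frequencies do not sum to 1: {self}")


@dataclass(frozen=True)
class ModelProbabilities:
    """Probability that a random sample qualifies under each model."""

    p_dom: float
    p_rec: float
    p_2het: float


@dataclass(frozen=True)
class GeneModelCounts:
    """Per-gene, per-stratum 2x2 carrier counts for one model."""

    gene: str
    stratum: str
    model: Model
    n1: int  # cases with qualifying alleles
    n2: int  # cases without
    n3: int  # controls with
    n4: int  # controls without


def genotype_freqs_from_counts(
    ac: int, an: int, nhomalt: int | None = None
) -> GenotypeFrequencies:
    """Genotype frequencies from summary counts.

    With the homozygous-alternate genotype count available (as in gnomAD) the
    frequencies are exact: p2 = nhomalt/(an/2), p1 = (ac - 2*nhomalt)/(an/2).
    Without it, Hardy-Weinberg equilibrium is assumed at allele frequency
    ac/an — convenient, though not exact under inbreeding or strong selection.
    """
    if an <= 0:
        raise ValueError("an must be positive")
    if ac < 0 or ac > an:
        raise ValueError(f"inconsistent counts ac={ac} an={an}")
    n_samples = an / 2.0
    if nhomalt is None:
        q = ac / an
        return GenotypeFrequencies((1 - q) ** 2, 2 * q * (1 - q), q * q)
    if 2 * nhomalt > ac:
        raise ValueError(f"2*nhomalt={2 * nhomalt} exceeds ac={ac}")
    p2 = nhomalt / n_samples
    p1 = (ac - 2 * nhomalt) / n_samples
    if p1 + p2 > 1.0 + 1e-9:
        raise ValueError(f"carrier frequency above 1 from ac={ac} an={an}")
    return GenotypeFrequencies(max(0.0, 1.0 - p1 - p2), p1, p2)


def model_probabilities(
    freqs: Sequence[GenotypeFrequencies],
) -> ModelProbabilities:
    """Qualifying-sample probabilities under the three models.

    Assumes the variants are independent; see the module docstring for the
    closed forms.  A single variant gives p_DOM = 1 - p0, p_REC = p2,
    p_2HET = 0.
    """
    if not freqs:
        raise ValueError("at least one variant required")
    p0 = np.array([f.p0 for f in freqs])
    p2 = np.array([f.p2 for f in freqs])
    if len(freqs) == 1:
        return ModelProbabilities(
            p_dom=float(1.0 - p0[0]), p_rec=float(p2[0]), p_2het=0.0
        )
    prod_all = float(np.prod(p0))
    carrier = 1.0 - p0
    # prod over k != i (and k != i,j); p0 == 0 handled by direct re-products
    if np.all(p0 > 0.0):
        prod_excl = prod_all / p0
        m = len(freqs)
        pair_sum = 0.0
        for i in range(m - 1):
            prod_excl_ij = prod_excl[i] / p0[i + 1 :]
            pair_sum += float(
                carrier[i] * np.sum(carrier[i + 1 :] * prod_excl_ij)
            )
        rec_single = float(np.sum(p2 * prod_excl))
    else:
        m = len(freqs)
        pair_sum = 0.0
        rec_single = 0.0
        for i in range(m):
            others = np.delete(p0, i)
            rec_single += p2[i] * float(np.prod(others))
            for j in range(i + 1, m):
                rest = np.delete(p0, [i, j])
                pair_sum += carrier[i] * carrier[j] * float(np.prod(rest))
    p_dom = 1.0 - prod_all
    p_2het = pair_sum
    p_rec = rec_single + p_2het
    return ModelProbabilities(p_dom=p_dom, p_rec=min(p_rec, p_dom), p_2het=p_2het)


def expected_control_counts(
    probs: ModelProbabilities, n_controls: int
) -> dict[Model, tuple[int, int]]:
    """(n3, n4) per model: probability scaled to the control cohort size.

    Rounded to the nearest integer, ties to even.
    """
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    out: dict[Model, tuple[int, int]] = {}
    for model, p in (
        ("DOM", probs.p_dom),
        ("REC", probs.p_rec),
        ("2HET", probs.p_2het),
    ):
        n3 = int(np.round(p * n_controls))
        out[model] = (n3, n_controls - n3)
    return out


def case_counts_from_genotypes(
    genotypes: np.ndarray,
    ld_pair_pvalues: Mapping[tuple[int, int], float] | None = None,
    ld_p_threshold: float = 0.1,
) -> dict[Model, int]:
    """Qualifying case counts from a samples x qualified-variants genotype matrix.

    Entries are 0/1/2 alternate-allele counts (missing coded as 0 upstream).
    ``ld_pair_pvalues`` maps column-index pairs (i < j) to LD-test P values; a
    sample qualifying for the recessive or double-heterozygous model *solely*
    through heterozygous variant pairs flagged as in LD (P < threshold) is not
    counted for that model.  The dominant model is unaffected by LD.
    """
    gm = np.asarray(genotypes)
    if gm.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (samples x variants)")
    totals = gm.sum(axis=1)
    n_variants_hit = (gm >= 1).sum(axis=1)
    dom = totals >= 1
    rec = totals >= 2
    het2 = n_variants_hit >= 2
    if ld_pair_pvalues:
        flagged = {
            tuple(sorted(pair))
            for pair, p in ld_pair_pvalues.items()
            if p < ld_p_threshold
        }
        for s in np.flatnonzero(het2):
            carried = np.flatnonzero(gm[s] >= 1)
            if np.any(gm[s] >= 2):
                continue  # a homozygous variant qualifies REC regardless of LD
            pairs = [
                (int(i), int(j))
                for a, i in enumerate(carried)
                for j in carried[a + 1 :]
            ]
            if all(p in flagged for p in pairs):
                # every supporting het pair is LD-linked: likely one haplotype
                rec[s] = False
                het2[s] = False
    return {"DOM": int(dom.sum()), "REC": int(rec.sum()), "2HET": int(het2.sum())}


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def prune_control_variants_for_ld(
    variant_afs: Mapping[str, float],
    ld_pairs: Iterable[tuple[str, str]],
) -> set[str]:
    """Keep one representative per connected LD component (highest AF).

    ``ld_pairs`` should already be restricted to confidently linked pairs
    (e.g. FDR < 0.05).  Within each connected component of the LD graph only
    the variant with the highest allele frequency survives; AF ties break to
    the lexicographically smallest variant key.  Used only when estimating
    control counts for the recessive / double-heterozygous models.
    """
    uf = _UnionFind(variant_afs)
    for a, b in ld_pairs:
        if a in variant_afs and b in variant_afs:
            uf.union(a, b)
    components: dict[str, list[str]] = {}
    for v in variant_afs:
        components.setdefault(uf.find(v), []).append(v)
    kept: set[str] = set()
    for members in components.values():
        kept.add(max(members, key=lambda v: (variant_afs[v], _neg_key(v))))
    return kept


class _neg_key:
    """Orders lexicographically smaller strings as larger, for max() tie-breaks."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_neg_key") -> bool:
        return self.s > other.s
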