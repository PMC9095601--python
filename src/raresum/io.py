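"""Reading and writing the formats the framework touches.

Cases arrive either as a jointly called multi-sample VCF (full genotypes) or
as per-variant summary counts; controls are always summary counts in the
gnomAD style (INFO fields AC / AN / nhomalt, optionally per ethnicity, sex and
subset).  Everything is normalized into :class:`VariantSummary` records, one
per biallelic alt allele; multiallelic sites are decomposed.

Coordinates are 1-based fully closed as in VCF.  AN is the total allele
number (2 x called samples for diploid autosomes); the number of called
samples for a variant is AN / 2.  Half-calls (e.g. ``./1``) are treated as
missing for that sample and variant.  Indels are consumed as-is; input is
assumed left-normalized upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF


class ConfigurationError(ValueError):
    """A required field or configuration entry is missing."""


StratumCounts = tuple[int, int, int | None]  # (ac, an, nhomalt)


@dataclass
class VariantSummary:
    """Summary counts and annotations of one biallelic alt allele."""

    chrom: str
    pos: int
    ref: str
    alt: str
    ac: int
    an: int
    nhomalt: int | None = None
    filter_status: str = "PASS"
    per_stratum: dict[str, StratumCounts] = field(default_factory=dict)
    annotations: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ac < 0 or self.an < 0 or self.ac > self.an:
            raise ValueError(f"inconsistent counts at {self.key}: ac={self.ac} an={self.an}")
        if self.nhomalt is not None and 2 * self.nhomalt > self.ac:
            raise ValueError(f"2*nhomalt > ac at {self.key}")

    @property
    def key(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"

    @property
    def passed(self) -> bool:
        return self.filter_status == "PASS"

    @property
    def af(self) -> float:
        return self.ac / self.an if self.an > 0 else float("nan")

    @property
    def n_samples(self) -> float:
        return self.an / 2.0

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)


@dataclass
class CoverageTrack:
    """Per-position fractions of samples with depth >= each threshold."""

    thresholds: tuple[int, ...]
    fractions: dict[tuple[str, int], np.ndarray]

    def fraction_at(self, chrom: str, pos: int, depth_threshold: int) -> float:
        """Fraction of samples covered to at least ``depth_threshold``.

        Positions absent from the track are treated as uncovered (0.0).
        """
        arr = self.fractions.get((chrom, pos))
        if arr is None:
            return 0.0
        try:
            idx = self.thresholds.index(depth_threshold)
        except ValueError:
            raise KeyError(
                f"threshold {depth_threshold} not summarized; have {self.thresholds}"
            ) from None
        return float(arr[idx])


def genotype_summary_stats(
    gt: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ac, an, nhomalt) per variant column of a dosage matrix (-1 = missing).

    Processed in column blocks so the boolean temporaries stay cache-sized.
    """
    n, m = gt.shape
    ac = np.empty(m, dtype=np.int64)
    an = np.empty(m, dtype=np.int64)
    nhom = np.empty(m, dtype=np.int64)
    step = 2048
    for j0 in range(0, m, step):
        blk = gt[:, j0 : j0 + step]
        n_missing = (blk == -1).sum(axis=0)
        sl = slice(j0, j0 + blk.shape[1])
        # each missing entry contributes -1 to the plain sum
        ac[sl] = blk.sum(axis=0, dtype=np.int64) + n_missing
        an[sl] = 2 * (n - n_missing)
        nhom[sl] = (blk == 2).sum(axis=0)
    return ac, an, nhom


@dataclass
class GenotypeMatrix:
    """Samples x variants alternate-allele dosages (0/1/2, -1 = missing)."""

    samples: list[str]
    variants: list[VariantSummary]
    genotypes: np.ndarray
    ethnicity: dict[str, str] = field(default_factory=dict)
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.samples), len(self.variants)):
            raise ValueError("genotype matrix shape does not match registries")

    def column(self, j: int) -> np.ndarray:
        return self.genotypes[:, j]

    def sample_indices(self, labels: Sequence[str] | None = None) -> np.ndarray:
        if labels is None:
            return np.arange(len(self.samples))
        keep = [
            i
            for i, s in enumerate(self.samples)
            if self.ethnicity.get(s, "other") in labels
        ]
        return np.array(keep, dtype=int)


@dataclass(frozen=True)
class SummaryFieldConfig:
    """Names of the INFO fields holding summary counts.

    ``strata`` lists stratum labels whose counts live in suffixed fields
    (e.g. ``AC_nfe``); ``extra_stratum_fields`` lists fully spelled-out extra
    labels (e.g. ``controls_nfe_female``) read the same way.  ``strict``
    controls whether a missing nhomalt field is an error or a recorded
    fallback to Hardy-Weinberg genotype frequencies.
    """

    ac: str = "AC"
    an: str = "AN"
    nhomalt: str = "nhomalt"
    strata: tuple[str, ...] = ()
    extra_stratum_fields: tuple[str, ...] = ()
    strict: bool = True


def _info_per_alt(value, n_alt: int, alt_index: int) -> int | None:
    if value is None:
        return None
    if isinstance(value, (tuple, list, np.ndarray)):
        return int(value[alt_index])
    return int(value) if n_alt == 1 else None


#: INFO field -> annotation key for functional annotations carried in the VCF
ANNOTATION_FIELDS = {
    "GENE": "gene",
    "CSQ": "consequence",
    "REVEL": "REVEL",
    "AF_popmax": "AF_popmax",
}


def _read_annotations(v) -> dict[str, object]:
    out: dict[str, object] = {}
    for field_name, key in ANNOTATION_FIELDS.items():
        value = v.INFO.get(field_name)
        if value is not None:
            if isinstance(value, bytes):
                value = value.decode()
            out[key] = value
    return out


def read_summary_vcf(
    path: str | Path, fields: SummaryFieldConfig | None = None
) -> list[VariantSummary]:
    """Read gnomAD-style summary counts into VariantSummary records.

    Emits one record per alt allele; multiallelic sites are decomposed into
    separate records sharing chrom/pos/ref.  A missing mandatory INFO field
    raises :class:`ConfigurationError` naming the field.
    """
    fields = fields or SummaryFieldConfig()
    out: list[VariantSummary] = []
    for v in VCF(str(path)):
        n_alt = len(v.ALT)
        an = v.INFO.get(fields.an)
        if an is None:
            raise ConfigurationError(
                f"INFO field {fields.an!r} missing at {v.CHROM}:{v.POS}"
            )
        for j, alt in enumerate(v.ALT):
            ac = _info_per_alt(v.INFO.get(fields.ac), n_alt, j)
            if ac is None:
                raise ConfigurationError(
                    f"INFO field {fields.ac!r} missing at {v.CHROM}:{v.POS}"
                )
            nhom = _info_per_alt(v.INFO.get(fields.nhomalt), n_alt, j)
            annotations: dict[str, object] = _read_annotations(v)
            if nhom is None and fields.strict:
                raise ConfigurationError(
                    f"INFO field {fields.nhomalt!r} missing at {v.CHROM}:{v.POS}"
                )
            if nhom is None:
                annotations["hwe_fallback"] = True
            per_stratum: dict[str, StratumCounts] = {}
            labels = list(fields.strata) + list(fields.extra_stratum_fields)
            for label in labels:
                s_ac = _info_per_alt(v.INFO.get(f"{fields.ac}_{label}"), n_alt, j)
                s_an = v.INFO.get(f"{fields.an}_{label}")
                if s_ac is None or s_an is None:
                    raise ConfigurationError(
                        f"stratum INFO fields for {label!r} missing at "
                        f"{v.CHROM}:{v.POS}"
                    )
                s_nhom = _info_per_alt(
                    v.INFO.get(f"{fields.nhomalt}_{label}"), n_alt, j
                )
                per_stratum[label] = (int(s_ac), int(s_an), s_nhom)
            out.append(
                VariantSummary(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    ac=int(ac),
                    an=int(an),
                    nhomalt=nhom,
                    filter_status=v.FILTER or "PASS",
                    per_stratum=per_stratum,
                    annotations=annotations,
                )
            )
    return out


def read_case_genotypes(
    path: str | Path, ethnicity: Mapping[str, str] | None = None
) -> GenotypeMatrix:
    """Read a jointly called multi-sample VCF into a genotype matrix.

    Genotypes are coded as alternate-allele dosage per decomposed alt allele;
    any genotype containing a missing allele (``./.`` or half-calls) is coded
    -1.  Per-genotype depth (FORMAT/DP) is retained when present.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    variants: list[VariantSummary] = []
    depth_cols: list[np.ndarray] = []
    have_depth = False
    for v in vcf:
        gts = np.array([g[:-1] for g in v.genotypes], dtype=int)  # drop phase flag
        missing = np.any(gts < 0, axis=1)
        try:
            dp = v.format("DP")
            dp = dp[:, 0].astype(int) if dp is not None else None
        except Exception:
            dp = None
        for j, alt in enumerate(v.ALT):
            allele_idx = j + 1
            dosage = (gts == allele_idx).sum(axis=1)
            dosage[missing] = -1
            called = int((~missing).sum())
            an = 2 * called
            ac = int(dosage[dosage > 0].sum())
            nhom = int((dosage == 2).sum())
            columns.append(dosage.astype(np.int8))
            variants.append(
                VariantSummary(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    ac=ac,
                    an=an,
                    nhomalt=nhom,
                    filter_status=v.FILTER or "PASS",
                    annotations=_read_annotations(v),
                )
            )
            if dp is not None:
                have_depth = True
                depth_cols.append(dp)
            else:
                depth_cols.append(np.full(len(samples), -1))
    genotypes = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    depths = np.stack(depth_cols, axis=1) if (columns and have_depth) else None
    return GenotypeMatrix(
        samples=samples,
        variants=variants,
        genotypes=genotypes,
        ethnicity=dict(ethnicity or {}),
        depths=depths,
    )


def read_coverage_bed(
    path: str | Path, thresholds: Sequence[int]
) -> CoverageTrack:
    """Read a BED-like coverage summary (0-based half-open intervals).

    Columns: chrom, start, end, then one fraction column per threshold.
    Intervals are expanded to 1-based positions internally.
    """
    thresholds = tuple(int(t) for t in thresholds)
    fractions: dict[tuple[str, int], np.ndarray] = {}
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] != 3 + len(thresholds):
        raise ConfigurationError(
            f"coverage file has {df.shape[1]} columns; expected "
            f"{3 + len(thresholds)} for thresholds {thresholds}"
        )
    for row in df.itertuples(index=False):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        vals = np.array(row[3:], dtype=float)
        for pos in range(start + 1, end + 1):  # to 1-based closed
            fractions[(chrom, pos)] = vals
    return CoverageTrack(thresholds=thresholds, fractions=fractions)


RESULT_COLUMNS = [
    "gene",
    "model",
    "stratum",
    "n1",
    "n2",
    "n3",
    "n4",
    "p_value",
    "odds_ratio",
    "p_adjusted",
    "variants",
]


def write_results_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write per-gene burden results as TSV (header always present)."""
    df = results.copy()
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = pd.Series(dtype=object)
    df = df[RESULT_COLUMNS + [c for c in df.columns if c not in RESULT_COLUMNS]]
    df.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ld_pairs(pairs, path: str | Path) -> None:
    """Serialize an LD-pair store as TSV."""
    rows = [
        {
            "key1": p.key1,
            "key2": p.key2,
            "stratum": p.stratum,
            "theta_hat": p.theta_hat,
            "statistic": p.statistic,
            "p_value": p.p_value,
            "fdr": p.fdr,
            "distance_bp": p.distance_bp,
            "high_ld": p.high_ld,
        }
        for p in pairs
    ]
    pd.DataFrame(
        rows,
        columns=[
            "key1",
            "key2",
            "stratum",
            "theta_hat",
            "statistic",
            "p_value",
            "fdr",
            "distance_bp",
            "high_ld",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_ld_pairs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
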