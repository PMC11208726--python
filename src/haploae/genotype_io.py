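"""Genotype ingestion, variant filtering and the additive dosage matrix.

Downstream modules consume a samples x SNPs matrix of minor-allele dosages
in {0, 1, 2}.  This module reads VCF (via cyvcf2) or a plain TSV matrix
with a JSON variant manifest, applies the standard common-variant filters
(zero missingness, MAF > 0.01) and performs additive recoding so that
every column counts copies of the *minor* allele.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call, distinct from any valid dosage.
MISSING: int = -1


@dataclass(frozen=True)
class VariantRecord:
    """Identity and frequency summary of one biallelic SNP.

    ``minor_allele`` records which of ref/alt is the counted (minor)
    allele after additive recoding; ``maf`` is its frequency in the same
    samples as the dosage column.
    """

    id: str
    chrom: str
    pos_bp: int  # 1-based
    ref_allele: str
    alt_allele: str
    minor_allele: str = "alt"  # "ref" | "alt"
    maf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"pos_bp must be >= 1, got {self.pos_bp}")
        if self.minor_allele not in ("ref", "alt"):
            raise ValueError(f"minor_allele must be 'ref' or 'alt', got {self.minor_allele!r}")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosage matrix plus per-variant metadata.

    ``dosages`` holds entries in {0, 1, 2} or :data:`MISSING`.  Variants
    are kept sorted by (chrom, pos_bp); the column order of ``dosages``
    matches ``variants``.
    """

    dosages: np.ndarray
    variants: list[VariantRecord]
    sample_ids: list[str]
    phenotype: Optional[np.ndarray] = None  # per-sample case/control labels

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"{self.dosages.shape[1]} dosage columns but {len(self.variants)} variants"
            )
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"{self.dosages.shape[0]} dosage rows but {len(self.sample_ids)} sample ids"
            )
        valid = np.isin(self.dosages, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"invalid dosage values {bad.tolist()}; expected 0/1/2 or MISSING")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos_bp for v in self.variants], dtype=np.int64)

    @property
    def snp_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def take_variants(self, index: Sequence[int]) -> "GenotypeMatrix":
        """Subset columns, preserving order of ``index``."""
        index = np.asarray(index, dtype=np.intp)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            variants=[self.variants[i] for i in index],
            sample_ids=list(self.sample_ids),
            phenotype=self.phenotype,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.dosages, other.dosages)
            and self.variants == other.variants
            and self.sample_ids == other.sample_ids
        )


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, span = region.partition(":")
    if not span:
        return chrom, 1, 2**62
    lo, _, hi = span.partition("-")
    return chrom, int(lo), int(hi) if hi else 2**62


def read_vcf(path: str | Path, region: Optional[str] = None) -> GenotypeMatrix:
    """Read a (plain or bgzipped) VCF into ALT-allele dosage counts.

    Multi-allelic sites are dropped (count logged); missing calls are kept
    as :data:`MISSING`.  ``region`` is ``chrom`` or ``chrom:start-end``
    (1-based inclusive), applied in-stream so no index is required.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad files
        raise ValueError(f"malformed VCF {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    want = _parse_region(region) if region else None

    columns: list[np.ndarray] = []
    variants: list[VariantRecord] = []
    n_multiallelic = 0
    for v in vcf:
        if want is not None:
            chrom, lo, hi = want
            if v.CHROM != chrom or not (lo <= v.POS <= hi):
                continue
        if len(v.ALT) != 1:
            n_multiallelic += 1
            continue
        gts = np.asarray([g[:2] for g in v.genotypes], dtype=np.int16)
        col = np.where((gts < 0).any(axis=1), MISSING, (gts > 0).sum(axis=1, dtype=np.int16))
        columns.append(col.astype(np.int16))
        variants.append(
            VariantRecord(
                id=v.ID or f"{v.CHROM}:{v.POS}",
                chrom=v.CHROM,
                pos_bp=v.POS,
                ref_allele=v.REF,
                alt_allele=v.ALT[0],
            )
        )
    if n_multiallelic:
        logger.info("dropped %d multi-allelic site(s)", n_multiallelic)
    if not variants:
        warnings.warn(f"no variants read from {path}" + (f" in region {region}" if region else ""))
        return GenotypeMatrix(
            np.empty((len(sample_ids), 0), dtype=np.int16), [], sample_ids
        )
    order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos_bp))
    dosages = np.column_stack([columns[i] for i in order])
    return GenotypeMatrix(dosages, [variants[i] for i in order], sample_ids)


def _allele_freq(col: np.ndarray) -> float:
    """Frequency of the counted allele, ignoring MISSING entries."""
    obs = col[col != MISSING]
    if obs.size == 0:
        return 0.0
    return float(obs.sum()) / (2 * obs.size)


def additive_recode(g: GenotypeMatrix) -> GenotypeMatrix:
    """Make every column count the minor allele and record per-variant MAF.

    Columns whose counted-allele frequency exceeds 0.5 are flipped
    (d -> 2 - d) and their ``minor_allele`` switched; an exact 0.5 tie
    keeps the ALT allele as counted.  Idempotent.
    """
    dosages = g.dosages.copy()
    variants = []
    for j, v in enumerate(g.variants):
        freq = _allele_freq(dosages[:, j])
        if freq > 0.5:
            obs = dosages[:, j] != MISSING
            dosages[obs, j] = 2 - dosages[obs, j]
            minor = "ref" if v.minor_allele == "alt" else "alt"
            freq = _allele_freq(dosages[:, j])  # recompute: exact float symmetry
        else:
            minor = v.minor_allele
        variants.append(replace(v, minor_allele=minor, maf=freq))
    return GenotypeMatrix(dosages, variants, list(g.sample_ids), g.phenotype)


def filter_maf(g: GenotypeMatrix, threshold: float = 0.01) -> GenotypeMatrix:
    """Keep variants with MAF strictly above ``threshold`` (order-stable)."""
    if not (0.0 <= threshold < 0.5):
        raise ValueError(f"MAF threshold must lie in [0, 0.5), got {threshold}")
    keep = []
    for j, v in enumerate(g.variants):
        maf = v.maf if v.maf is not None else _allele_freq(g.dosages[:, j])
        maf = min(maf, 1.0 - maf)
        if maf > threshold:
            keep.append(j)
    removed = g.n_snps - len(keep)
    logger.info("filter_maf(>%g): kept %d, removed %d", threshold, len(keep), removed)
    return g.take_variants(keep)


def filter_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Drop every variant with at least one missing call."""
    keep = np.flatnonzero((g.dosages != MISSING).all(axis=0))
    if keep.size == 0 and g.n_snps > 0:
        warnings.warn("all variants have missing calls; result is empty")
    logger.info("filter_missing: kept %d, removed %d", keep.size, g.n_snps - keep.size)
    return g.take_variants(keep)


def standard_filter(g: GenotypeMatrix, maf_threshold: float = 0.01) -> GenotypeMatrix:
    """The fixed filtering pipeline: missingness -> additive recode -> MAF."""
    return filter_maf(additive_recode(filter_missing(g)), maf_threshold)


def write_dosage_matrix(g: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.tsv`` (samples x SNPs) and ``<prefix>.manifest.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = prefix.with_suffix(".tsv")
    manifest = prefix.with_suffix(".manifest.json")
    df = pd.DataFrame(g.dosages, index=g.sample_ids, columns=g.snp_ids)
    df.to_csv(tsv, sep="\t", index_label="sample_id")
    meta = {
        "n_samples": g.n_samples,
        "n_snps": g.n_snps,
        "variants": [
            {
                "id": v.id, "chrom": v.chrom, "pos_bp": v.pos_bp,
                "ref_allele": v.ref_allele, "alt_allele": v.alt_allele,
                "minor_allele": v.minor_allele, "maf": v.maf,
            }
            for v in g.variants
        ],
        "phenotype": g.phenotype.tolist() if g.phenotype is not None else None,
    }
    manifest.write_text(json.dumps(meta, indent=1))
    return tsv, manifest


def read_dosage_matrix(prefix: str | Path) -> GenotypeMatrix:
    """Inverse of :func:`write_dosage_matrix`; checks manifest/matrix agreement."""
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", index_col="sample_id")
    meta = json.loads(prefix.with_suffix(".manifest.json").read_text())
    if len(meta["variants"]) != df.shape[1] or meta["n_snps"] != df.shape[1]:
        raise ValueError(
            f"manifest lists {len(meta['variants'])} variants but matrix has {df.shape[1]} columns"
        )
    if meta["n_samples"] != df.shape[0]:
        raise ValueError(
            f"manifest lists {meta['n_samples']} samples but matrix has {df.shape[0]} rows"
        )
    variants = [VariantRecord(**rec) for rec in meta["variants"]]
    for v, col in zip(variants, df.columns):
        if v.id != str(col):
            raise ValueError(f"manifest/matrix SNP id mismatch: {v.id!r} vs {col!r}")
    phen = meta.get("phenotype")
    return GenotypeMatrix(
        df.to_numpy(dtype=np.int16),
        variants,
        [str(s) for s in df.index],
        phenotype=np.asarray(phen) if phen is not None else None,
    )
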