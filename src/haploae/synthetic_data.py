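"""Founder-haplotype genotype simulator.

Each simulated block carries K distinct founder haplotypes; every
individual draws two founders i.i.d. from the founder frequencies and
each inherited allele flips with a small mutation/noise probability.
This directly instantiates the structure haploblocks encode — a bounded
region harbouring only a few distinct haplotypes — with two knobs (K and
the flip rate) that tune the block's internal LD.  Panels concatenate
independent blocks with positional gaps and carry ground-truth
boundaries so block detection can be scored against the truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .genotype_io import GenotypeMatrix, VariantRecord
from .ld_blocks import Haploblock, average_pairwise_ld

SNP_SPACING_BP = 1_000
MAX_COLUMN_RETRIES = 100


@dataclass(frozen=True)
class BlockSimConfig:
    """One founder-haplotype block.

    ``founder_freq`` defaults to a symmetric Dirichlet(1) draw; columns
    whose realized MAF falls below ``maf_floor`` are redrawn.  SNP
    carrier sets are clades of a random founder genealogy, so founder
    haplotypes form a perfect phylogeny and within-block |D'| is 1
    before noise — the structure the confidence-interval block criterion
    assumes.
    """

    n_snps: int
    n_founders: int = 4
    founder_freq: Optional[tuple[float, ...]] = None
    mutation_rate: float = 0.002
    maf_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if not (0.0 <= self.mutation_rate < 0.5):
            raise ValueError("mutation_rate must lie in [0, 0.5)")
        if self.founder_freq is not None:
            f = np.asarray(self.founder_freq, dtype=float)
            if f.size != self.n_founders or not np.isclose(f.sum(), 1.0):
                raise ValueError("founder_freq must have n_founders entries summing to 1")


@dataclass(frozen=True)
class PanelSimConfig:
    """A chromosome-like panel of mutually independent blocks."""

    n_samples: int
    blocks: tuple[BlockSimConfig, ...]
    inter_block_gap_bp: int = 1_000_000
    chrom: str = "22"
    seed: int = 0


def _founder_clades(K: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Clades of a random binary genealogy over K founders.

    Built by repeatedly coalescing two random lineages; returns every
    clade except the root's full founder set (singletons included).
    Carrier sets drawn from one tree are nested or disjoint, i.e. the
    founders form a perfect phylogeny.
    """
    active: list[frozenset[int]] = [frozenset([k]) for k in range(K)]
    clades: list[frozenset[int]] = list(active)
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        merged = active[i] | active[j]
        del active[j], active[i]
        active.append(merged)
        if len(merged) < K:
            clades.append(merged)
    return [np.fromiter(c, dtype=np.intp) for c in clades]


def _draw_structure(cfg: BlockSimConfig, rng: np.random.Generator
                    ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Founder frequencies plus genealogy clades, jointly rejected so the
    MAF floor is attainable (some clade's frequency sum lies in
    [maf_floor, 1 - maf_floor])."""
    for _ in range(MAX_COLUMN_RETRIES):
        if cfg.founder_freq is not None:
            freq = np.asarray(cfg.founder_freq, dtype=float)
        else:
            freq = rng.dirichlet(np.ones(cfg.n_founders))
        clades = _founder_clades(cfg.n_founders, rng)
        usable = [c for c in clades
                  if cfg.maf_floor <= freq[c].sum() <= 1.0 - cfg.maf_floor]
        if usable:
            return freq, usable
        if cfg.founder_freq is not None and cfg.n_founders == 2:
            break  # clades for K=2 are fixed; retrying cannot help
    raise ValueError(
        f"no clade of the founder genealogy reaches MAF >= {cfg.maf_floor}; "
        "lower maf_floor or rebalance founder_freq"
    )


def simulate_block(cfg: BlockSimConfig, n_samples: int,
                   seed: int | np.random.Generator = 0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Dosage columns for one block; returns (dosages, founder_pairs).

    Founder haplotypes are binary vectors: each SNP's minor allele is
    carried by one clade of a per-block random founder genealogy, so the
    founders form a perfect phylogeny (within-block |D'| = 1 before
    noise).  Individuals inherit two founders i.i.d. from the founder
    frequencies; every inherited allele flips with the mutation rate;
    dosage is the allele sum.  Columns failing the MAF floor are redrawn
    a bounded number of times.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freq, clades = _draw_structure(cfg, rng)
    pairs = rng.choice(cfg.n_founders, size=(n_samples, 2), p=freq)
    dosages = np.empty((n_samples, cfg.n_snps), dtype=np.int16)
    for s in range(cfg.n_snps):
        for attempt in range(MAX_COLUMN_RETRIES):
            pattern = np.zeros(cfg.n_founders, dtype=np.int16)
            pattern[clades[rng.integers(len(clades))]] = 1
            alleles = pattern[pairs]  # (n_samples, 2)
            if cfg.mutation_rate > 0:
                flips = rng.random((n_samples, 2)) < cfg.mutation_rate
                alleles = alleles ^ flips
            col = alleles.sum(axis=1)
            f = col.mean() / 2.0
            maf = min(f, 1.0 - f)
            if maf >= cfg.maf_floor:
                if f > 0.5:  # keep columns minor-allele coded
                    col = 2 - col
                dosages[:, s] = col
                break
        else:
            raise RuntimeError(
                f"could not draw a column with MAF >= {cfg.maf_floor} in "
                f"{MAX_COLUMN_RETRIES} tries; lower maf_floor or change founder_freq"
            )
    return dosages, pairs


def simulate_panel(cfg: PanelSimConfig) -> tuple[GenotypeMatrix, list[Haploblock]]:
    """Concatenate independent blocks into a panel with true boundaries."""
    rng = np.random.default_rng(cfg.seed)
    sample_ids = [f"S{i:05d}" for i in range(cfg.n_samples)]
    col_blocks, variants, truth = [], [], []
    pos = 1
    idx = 0
    for b, bcfg in enumerate(cfg.blocks):
        dos, _ = simulate_block(bcfg, cfg.n_samples, rng)
        col_blocks.append(dos)
        first_idx, start_bp = idx, pos
        for s in range(bcfg.n_snps):
            maf = min(dos[:, s].mean() / 2.0, 1.0 - dos[:, s].mean() / 2.0)
            variants.append(VariantRecord(
                id=f"b{b:03d}_s{s:03d}", chrom=cfg.chrom, pos_bp=pos,
                ref_allele="A", alt_allele="G", minor_allele="alt", maf=float(maf),
            ))
            pos += SNP_SPACING_BP
            idx += 1
        truth.append(Haploblock(
            chrom=cfg.chrom, first_idx=first_idx, last_idx=idx - 1,
            start_bp=start_bp, end_bp=pos - SNP_SPACING_BP,
            snp_ids=[v.id for v in variants[first_idx:idx]],
        ))
        pos += cfg.inter_block_gap_bp
    g = GenotypeMatrix(np.hstack(col_blocks), variants, sample_ids)
    for blk in truth:
        blk.avg_pairwise_ld = average_pairwise_ld(g, blk)
    return g, truth


def default_panel_config(n_samples: int = 2000, n_blocks: int = 50, seed: int = 0,
                         k_range: tuple[int, int] = (2, 6),
                         mutation_rate: float = 0.005,
                         mean_snps: int = 25) -> PanelSimConfig:
    """Chromosome-scale fixture: ~50 blocks with positively skewed sizes.

    Block sizes follow a log-normal-like distribution with mean near
    ``mean_snps`` (most blocks small, a few populated), founder counts
    uniform over ``k_range`` so the panel's internal LD spans both sides
    of the 0.4 selection threshold.
    """
    rng = np.random.default_rng(seed)
    sigma = 0.5
    mu = np.log(mean_snps) - sigma**2 / 2
    sizes = np.maximum(3, np.round(rng.lognormal(mu, sigma, size=n_blocks))).astype(int)
    blocks = tuple(
        BlockSimConfig(
            n_snps=int(sz),
            n_founders=int(rng.integers(k_range[0], k_range[1] + 1)),
            mutation_rate=mutation_rate,
        )
        for sz in sizes
    )
    return PanelSimConfig(n_samples=n_samples, blocks=blocks, seed=seed)


def _measure_avg_ld(cfg: BlockSimConfig, n_probe: int, rng: np.random.Generator) -> float:
    dos, _ = simulate_block(cfg, n_probe, rng)
    g = GenotypeMatrix(
        dos,
        [VariantRecord(id=f"s{k}", chrom="1", pos_bp=1 + k * SNP_SPACING_BP,
                       ref_allele="A", alt_allele="G") for k in range(cfg.n_snps)],
        [f"S{i}" for i in range(n_probe)],
    )
    blk = Haploblock("1", 0, cfg.n_snps - 1, 1, 1 + (cfg.n_snps - 1) * SNP_SPACING_BP,
                     [f"s{k}" for k in range(cfg.n_snps)])
    return average_pairwise_ld(g, blk)


def calibrate_ld(cfg: BlockSimConfig, target_avg_ld: float, n_probe: int = 2000,
                 seed: int = 0, tol: float = 0.05) -> tuple[BlockSimConfig, float]:
    """Tune (K, mutation rate) until simulated average pairwise r2 hits target.

    Average r2 decreases in both the founder count and the flip rate, so
    for each K (small to large) the flip rate is bisected; the first
    configuration within ``tol`` of the target is returned together with
    its achieved value.
    """
    if not (0.0 < target_avg_ld < 1.0):
        raise ValueError("target_avg_ld must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    best: tuple[Optional[BlockSimConfig], float] = (None, float("inf"))
    for K in range(2, 13):
        lo, hi = 0.0, 0.3  # avg r2 decreases in the flip rate
        for _ in range(12):
            eps = (lo + hi) / 2
            cand = replace(cfg, n_founders=K, mutation_rate=eps, founder_freq=None)
            achieved = _measure_avg_ld(cand, n_probe, rng)
            if abs(achieved - target_avg_ld) <= tol:
                return cand, achieved
            if abs(achieved - target_avg_ld) < abs(best[1] - target_avg_ld):
                best = (cand, achieved)
            if achieved > target_avg_ld:
                lo = eps
            else:
                hi = eps
    raise RuntimeError(
        f"target {target_avg_ld} unreachable; closest achieved {best[1]:.3f} "
        f"with {best[0]}"
    )
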