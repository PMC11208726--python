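"""Pairwise LD estimation and confidence-interval haploblock detection.

Two-locus haplotype frequencies are estimated from unphased dosages with
an EM algorithm (only the double-heterozygote cell is phase-ambiguous).
From the fitted frequencies we compute D, D' and r2, and a likelihood
profile over D' yields the Gabriel-style confidence interval used to
classify each SNP pair as strong LD, strong historical recombination, or
non-informative.  A haploblock is a contiguous run of SNPs whose endpoint
pair is strong LD and in which at least ``inform_frac`` of the informative
pairs are strong LD; candidate runs are accepted greedily by size.

Default thresholds follow the calibrated block-detection parameters:
strong-LD confidence interval [0.5, 0.85], recombination upper bound 0.7,
and a 10 Mb scan window.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .genotype_io import GenotypeMatrix

EM_TOL = 1e-7
EM_MAX_ITER = 1000
CI_GRID_POINTS = 101


class PairClass(enum.Enum):
    STRONG_LD = "strong_ld"
    STRONG_RECOMB = "strong_recomb"
    NONINFORMATIVE = "noninformative"


@dataclass(frozen=True)
class BlockConfig:
    """Thresholds for pair classification and block acceptance."""

    strong_low: float = 0.5
    strong_high: float = 0.85
    recomb_high: float = 0.7
    inform_frac: float = 0.95
    max_window_bp: int = 10_000_000
    min_block_snps: int = 2
    confidence: float = 0.90

    def __post_init__(self) -> None:
        if not (0 < self.strong_low < self.strong_high <= 1):
            raise ValueError("need 0 < strong_low < strong_high <= 1")
        if not (self.recomb_high < self.strong_high):
            raise ValueError("need recomb_high < strong_high")


@dataclass(frozen=True)
class PairwiseLD:
    """LD summary for one SNP pair, including the D' confidence interval."""

    i: int
    j: int
    D: float
    Dprime: float
    r2: float
    ci_low: float
    ci_high: float
    pair_class: PairClass


@dataclass
class Haploblock:
    """A contiguous run of SNPs with high internal LD."""

    chrom: str
    first_idx: int
    last_idx: int  # inclusive
    start_bp: int
    end_bp: int
    snp_ids: list[str]
    avg_pairwise_ld: Optional[float] = None

    @property
    def size(self) -> int:
        return self.last_idx - self.first_idx + 1

    @property
    def index(self) -> np.ndarray:
        return np.arange(self.first_idx, self.last_idx + 1)


def _pair_counts(col_i: np.ndarray, col_j: np.ndarray) -> np.ndarray:
    """3x3 contingency table of dosage pairs."""
    if col_i.shape != col_j.shape:
        raise ValueError("dosage vectors differ in length")
    return np.bincount(3 * col_i.astype(np.intp) + col_j, minlength=9).reshape(3, 3)


def _em_from_counts(n: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER
                    ) -> tuple[np.ndarray, bool]:
    """EM for (pAB, pAb, paB, pab) from a 3x3 dosage-pair table.

    Returns the frequency vector and a flag that is False when either
    locus is monomorphic (degenerate pair).
    """
    total = n.sum()
    if total == 0:
        return np.full(4, 0.25), False
    pA = (2 * n[2, :].sum() + n[1, :].sum()) / (2 * total)
    pB = (2 * n[:, 2].sum() + n[:, 1].sum()) / (2 * total)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return np.full(4, 0.25), False

    # Unambiguous haplotype counts: every cell except the double het.
    # Haplotypes: AB=both minor, Ab=minor/major, aB, ab.
    base = np.array([
        2 * n[2, 2] + n[2, 1] + n[1, 2],  # AB
        2 * n[2, 0] + n[2, 1] + n[1, 0],  # Ab
        2 * n[0, 2] + n[0, 1] + n[1, 2],  # aB
        2 * n[0, 0] + n[0, 1] + n[1, 0],  # ab
    ], dtype=float)
    ndh = float(n[1, 1])

    p = np.full(4, 0.25)
    for _ in range(max_iter):
        coupling = p[0] * p[3]
        repulsion = p[1] * p[2]
        w = 0.5 if coupling + repulsion == 0 else coupling / (coupling + repulsion)
        counts = base + ndh * np.array([w, 1 - w, 1 - w, w])
        p_new = counts / (2 * total)
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            break
        p = p_new
    return p, True


def em_haplotype_freqs(col_i: np.ndarray, col_j: np.ndarray) -> tuple[np.ndarray, bool]:
    """Two-locus haplotype frequencies (pAB, pAb, paB, pab) via EM.

    The boolean flag is False for a degenerate (monomorphic) pair, in
    which case the pair is non-informative.
    """
    return _em_from_counts(_pair_counts(np.asarray(col_i), np.asarray(col_j)))


def em_log_likelihood(n: np.ndarray, p: np.ndarray) -> float:
    """Multinomial log-likelihood of a 3x3 table under haplotype freqs ``p``."""
    probs = _cell_probs(p[None, :])[0]
    with np.errstate(divide="ignore"):
        ll = np.where(n.ravel() > 0, n.ravel() * np.log(np.maximum(probs, 1e-300)), 0.0)
    return float(ll.sum())


def _cell_probs(p: np.ndarray) -> np.ndarray:
    """Genotype-pair cell probabilities for stacked haplotype freqs.

    ``p`` has shape (m, 4) ordered (AB, Ab, aB, ab); returns (m, 9) cells
    in row-major (g_i, g_j) order.
    """
    hAB, hAb, haB, hab = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    return np.stack([
        hab * hab,                    # (0,0)
        2 * hab * haB,                # (0,1)
        haB * haB,                    # (0,2)
        2 * hab * hAb,                # (1,0)
        2 * (hAB * hab + hAb * haB),  # (1,1)
        2 * hAB * haB,                # (1,2)
        hAb * hAb,                    # (2,0)
        2 * hAB * hAb,                # (2,1)
        hAB * hAB,                    # (2,2)
    ], axis=1)


def ld_statistics(freqs: Sequence[float]) -> tuple[float, float, float]:
    """(D, D', r2) from haplotype frequencies (pAB, pAb, paB, pab)."""
    pAB, pAb, paB, pab = (float(x) for x in freqs)
    pA = pAB + pAb
    pB = pAB + paB
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("allele frequency 0 or 1: LD undefined (noninformative pair)")
    D = pAB - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = 0.0 if dmax == 0 else abs(D) / dmax
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return D, min(dprime, 1.0), min(r2, 1.0)


def _dprime_profile(n: np.ndarray, confidence: float) -> Optional[tuple[float, float]]:
    """Likelihood-profile CI for |D'| on a 101-point grid in [0, 1].

    Allele frequencies are fixed at their sample MLEs; the sign of D is
    taken from the EM point estimate.  Likelihoods are normalized to a
    unit mass over the grid and the central ``confidence`` interval read
    off the cumulative mass.
    """
    total = n.sum()
    pA = (2 * n[2, :].sum() + n[1, :].sum()) / (2 * total)
    pB = (2 * n[:, 2].sum() + n[:, 1].sum()) / (2 * total)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return None
    p_hat, ok = _em_from_counts(n)
    if not ok:
        return None
    D_hat = p_hat[0] - (p_hat[0] + p_hat[1]) * (p_hat[0] + p_hat[2])
    sign = 1.0 if D_hat >= 0 else -1.0
    if sign > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    grid = np.linspace(0.0, 1.0, CI_GRID_POINTS)
    D = sign * grid * dmax
    hap = np.stack([
        pA * pB + D,
        pA * (1 - pB) - D,
        (1 - pA) * pB - D,
        (1 - pA) * (1 - pB) + D,
    ], axis=1)
    hap = np.clip(hap, 0.0, 1.0)
    cells = np.maximum(_cell_probs(hap), 1e-300)
    ll = (n.ravel()[None, :] * np.log(cells)).sum(axis=1)
    like = np.exp(ll - ll.max())
    mass = like / like.sum()
    cum = np.cumsum(mass)
    alpha = (1.0 - confidence) / 2.0
    lo_idx = int(np.searchsorted(cum, alpha, side="left"))
    tail = 1.0 - np.concatenate(([0.0], cum[:-1]))  # mass at >= each grid point
    hi_candidates = np.flatnonzero(tail >= alpha)
    hi_idx = int(hi_candidates[-1]) if hi_candidates.size else CI_GRID_POINTS - 1
    return float(grid[lo_idx]), float(grid[hi_idx])


def dprime_ci(col_i: np.ndarray, col_j: np.ndarray, confidence: float = 0.90
              ) -> Optional[tuple[float, float]]:
    """Confidence bounds (ci_low, ci_high) for |D'|; None if degenerate."""
    return _dprime_profile(_pair_counts(np.asarray(col_i), np.asarray(col_j)), confidence)


def classify_bounds(ci: Optional[tuple[float, float]], cfg: BlockConfig) -> PairClass:
    """Gabriel classification from CI bounds alone."""
    if ci is None:
        return PairClass.NONINFORMATIVE
    ci_low, ci_high = ci
    if ci_low >= cfg.strong_low and ci_high >= cfg.strong_high:
        return PairClass.STRONG_LD
    if ci_high < cfg.recomb_high:
        return PairClass.STRONG_RECOMB
    return PairClass.NONINFORMATIVE


def classify_pair(ld: PairwiseLD, cfg: BlockConfig) -> PairClass:
    return classify_bounds((ld.ci_low, ld.ci_high), cfg)


def pairwise_ld(g: GenotypeMatrix, i: int, j: int, cfg: BlockConfig = BlockConfig()
                ) -> PairwiseLD:
    """Full LD summary (EM point estimates + D' CI + class) for one pair."""
    n = _pair_counts(g.dosages[:, i], g.dosages[:, j])
    p, ok = _em_from_counts(n)
    ci = _dprime_profile(n, cfg.confidence) if ok else None
    if ok:
        D, dprime, r2 = ld_statistics(p)
    else:
        D = dprime = r2 = float("nan")
    lo, hi = ci if ci is not None else (float("nan"), float("nan"))
    return PairwiseLD(i, j, D, dprime, r2, lo, hi, classify_bounds(ci, cfg))


def _pair_class_matrix(g: GenotypeMatrix, cfg: BlockConfig) -> np.ndarray:
    """Class codes for all pairs within the bp window.

    Codes: 0 = not computed / noninformative, 1 = strong LD,
    2 = strong recombination.  Symmetric m x m int8 matrix.
    """
    m = g.n_snps
    pos = g.positions
    codes = np.zeros((m, m), dtype=np.int8)
    dos = np.ascontiguousarray(g.dosages)
    for i in range(m - 1):
        jmax = int(np.searchsorted(pos, pos[i] + cfg.max_window_bp, side="right"))
        for j in range(i + 1, jmax):
            ci = _dprime_profile(_pair_counts(dos[:, i], dos[:, j]), cfg.confidence)
            cls = classify_bounds(ci, cfg)
            if cls is PairClass.STRONG_LD:
                codes[i, j] = codes[j, i] = 1
            elif cls is PairClass.STRONG_RECOMB:
                codes[i, j] = codes[j, i] = 2
    return codes


def _greedy_select(candidates: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Pick non-overlapping spans, largest first (ties: leftmost start)."""
    chosen: list[tuple[int, int]] = []
    used: set[int] = set()
    for i, j in sorted(candidates, key=lambda c: (-(c[1] - c[0] + 1), c[0])):
        if any(k in used for k in range(i, j + 1)):
            continue
        chosen.append((i, j))
        used.update(range(i, j + 1))
    return sorted(chosen)


def find_blocks(g: GenotypeMatrix, cfg: BlockConfig = BlockConfig()
                ) -> tuple[list[Haploblock], list[int]]:
    """Partition one chromosome into haploblocks; returns (blocks, singletons).

    Candidate spans are contiguous index runs whose outermost pair is
    strong LD and whose bp extent fits the window; a span is accepted
    when, among its informative pairs (strong LD + strong recombination),
    the strong-LD fraction reaches ``cfg.inform_frac``.  Accepted spans
    are chosen greedily by descending SNP count, discarding overlaps.
    ``singletons`` lists the variant indices covered by no block.
    """
    chroms = {v.chrom for v in g.variants}
    if len(chroms) > 1:
        raise ValueError(
            f"find_blocks expects a single chromosome, got {sorted(chroms)}; "
            "invoke per chromosome"
        )
    m = g.n_snps
    if m < 2:
        return [], list(range(m))
    pos = g.positions
    codes = _pair_class_matrix(g, cfg)
    strong = (codes == 1).astype(np.int64)
    inform = (codes > 0).astype(np.int64)
    # 2-D prefix sums; submatrix sums over [i..j]x[i..j] count each
    # unordered pair twice (diagonal is zero).
    Ps = strong.cumsum(axis=0).cumsum(axis=1)
    Pi = inform.cumsum(axis=0).cumsum(axis=1)

    def boxsum(P: np.ndarray, i: int, j: int) -> int:
        s = P[j, j]
        if i > 0:
            s -= P[i - 1, j] + P[j, i - 1] - P[i - 1, i - 1]
        return int(s) // 2

    candidates: list[tuple[int, int]] = []
    for i in range(m - 1):
        jmax = int(np.searchsorted(pos, pos[i] + cfg.max_window_bp, side="right"))
        for j in range(i + max(1, cfg.min_block_snps - 1), jmax):
            if codes[i, j] != 1:  # endpoint pair must itself be strong LD
                continue
            n_strong = boxsum(Ps, i, j)
            n_inform = boxsum(Pi, i, j)
            if n_inform > 0 and n_strong / n_inform >= cfg.inform_frac:
                candidates.append((i, j))

    spans = _greedy_select(candidates)
    chrom = g.variants[0].chrom if g.variants else "?"
    blocks = []
    covered: set[int] = set()
    for i, j in spans:
        blocks.append(Haploblock(
            chrom=chrom,
            first_idx=i,
            last_idx=j,
            start_bp=int(pos[i]),
            end_bp=int(pos[j]),
            snp_ids=[g.variants[k].id for k in range(i, j + 1)],
        ))
        covered.update(range(i, j + 1))
    for b in blocks:
        b.avg_pairwise_ld = average_pairwise_ld(g, b)
    singletons = [k for k in range(m) if k not in covered]
    return blocks, singletons


def average_pairwise_ld(g: GenotypeMatrix, block: Haploblock, measure: str = "r2") -> float:
    """Mean pairwise LD (r2 by default, D' optionally) over a block."""
    idx = block.index
    if idx.size < 2:
        warnings.warn(f"singleton block at index {block.first_idx}: average LD undefined")
        return float("nan")
    vals = []
    for a in range(idx.size - 1):
        for b in range(a + 1, idx.size):
            p, ok = em_haplotype_freqs(g.dosages[:, idx[a]], g.dosages[:, idx[b]])
            if not ok:
                continue
            _, dprime, r2 = ld_statistics(p)
            vals.append(r2 if measure == "r2" else dprime)
    return float(np.mean(vals)) if vals else float("nan")


def write_blocks(blocks: Iterable[Haploblock], prefix: str | Path) -> tuple[Path, Path]:
    """Write PLINK-dialect ``<prefix>.blocks`` and ``<prefix>.blocks.det``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    blocks = list(blocks)
    bpath = prefix.parent / (prefix.name + ".blocks")
    dpath = prefix.parent / (prefix.name + ".blocks.det")
    with open(bpath, "w") as fh:
        for b in blocks:
            fh.write("* " + " ".join(b.snp_ids) + "\n")
    with open(dpath, "w") as fh:
        fh.write(f"{'CHR':>4} {'BP1':>12} {'BP2':>12} {'KB':>12} {'NSNPS':>8}  SNPS\n")
        for b in blocks:
            kb = (b.end_bp - b.start_bp + 1) / 1000.0
            fh.write(
                f"{b.chrom:>4} {b.start_bp:>12} {b.end_bp:>12} {kb:>12.3f} "
                f"{b.size:>8}  {'|'.join(b.snp_ids)}\n"
            )
    return bpath, dpath


def read_blocks(det_path: str | Path, g: GenotypeMatrix) -> list[Haploblock]:
    """Read a ``.blocks.det`` table and resolve SNP ids against ``g``.

    Accepts PLINK-produced files, so externally called blocks can be
    swapped in.
    """
    det_path = Path(det_path)
    id_to_idx = {v.id: k for k, v in enumerate(g.variants)}
    blocks = []
    with open(det_path) as fh:
        header = fh.readline().split()
        if header[:2] != ["CHR", "BP1"]:
            raise ValueError(f"{det_path}: not a .blocks.det file (header {header[:2]})")
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            chrom, bp1, bp2, _kb, _nsnps, snps = parts[0], *parts[1:5], parts[5]
            ids = snps.split("|")
            missing = [s for s in ids if s not in id_to_idx]
            if missing:
                raise ValueError(f"{det_path}: SNP ids absent from matrix: {missing}")
            idx = sorted(id_to_idx[s] for s in ids)
            blocks.append(Haploblock(
                chrom=chrom,
                first_idx=idx[0],
                last_idx=idx[-1],
                start_bp=int(bp1),
                end_bp=int(bp2),
                snp_ids=[g.variants[k].id for k in range(idx[0], idx[-1] + 1)],
            ))
    return blocks
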