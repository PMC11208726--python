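"""Haploblock detection against a brute-force oracle, plus block I/O."""

import numpy as np
import pytest

from haploae import (
    BlockConfig,
    PairClass,
    average_pairwise_ld,
    dprime_ci,
    find_blocks,
    read_blocks,
    write_blocks,
)
from haploae.ld_blocks import _greedy_select, classify_bounds

from conftest import make_matrix


def brute_force_blocks(g, cfg):
    """Enumerate every contiguous span and apply the acceptance predicate
    and greedy selection directly (no prefix sums)."""
    m, pos = g.n_snps, g.positions
    cls = {}
    for i in range(m - 1):
        for j in range(i + 1, m):
            if pos[j] - pos[i] <= cfg.max_window_bp:
                ci = dprime_ci(g.dosages[:, i], g.dosages[:, j], cfg.confidence)
                cls[(i, j)] = classify_bounds(ci, cfg)
    candidates = []
    for i in range(m - 1):
        for j in range(i + 1, m):
            if (i, j) not in cls or j - i + 1 < cfg.min_block_snps:
                continue
            if cls[(i, j)] is not PairClass.STRONG_LD:
                continue
            pairs = [cls[(a, b)] for a in range(i, j) for b in range(a + 1, j + 1)]
            s = sum(c is PairClass.STRONG_LD for c in pairs)
            r = sum(c is PairClass.STRONG_RECOMB for c in pairs)
            if s + r > 0 and s / (s + r) >= cfg.inform_frac:
                candidates.append((i, j))
    return _greedy_select(candidates)


def correlated_matrix(rng, n, n_snps, flip=0.02):
    """Columns copied from one template with small perturbations: high LD."""
    base = rng.integers(0, 3, n).astype(np.int16)
    cols = []
    for _ in range(n_snps):
        noise = rng.random(n) < flip
        col = np.where(noise, rng.integers(0, 3, n), base)
        cols.append(col)
    return np.column_stack(cols).astype(np.int16)


class TestFindBlocks:
    def test_all_strong_pairs_form_one_block(self):
        rng = np.random.default_rng(2)
        g = make_matrix(correlated_matrix(rng, 300, 3))
        blocks, singles = find_blocks(g)
        assert len(blocks) == 1 and blocks[0].size == 3
        assert singles == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_brute_force_oracle(self, seed, small_panel):
        rng = np.random.default_rng(seed)
        # mix of two correlated runs and independent noise columns, <= 12 SNPs
        left = correlated_matrix(rng, 200, 4)
        noise = rng.integers(0, 3, (200, 3)).astype(np.int16)
        right = correlated_matrix(rng, 200, 4)
        g = make_matrix(np.hstack([left, noise, right]))
        cfg = BlockConfig()
        blocks, _ = find_blocks(g, cfg)
        spans = [(b.first_idx, b.last_idx) for b in blocks]
        assert spans == brute_force_blocks(g, cfg)

    def test_window_prevents_distant_pairs(self):
        rng = np.random.default_rng(5)
        dos = correlated_matrix(rng, 300, 2, flip=0.0)
        g = make_matrix(dos, spacing=15_000_000)  # 15 Mb apart
        blocks, singles = find_blocks(g)
        assert blocks == []
        assert singles == [0, 1]

    def test_independent_columns_give_no_blocks(self):
        rng = np.random.default_rng(8)
        g = make_matrix(rng.binomial(2, 0.3, (400, 5)).astype(np.int16))
        blocks, singles = find_blocks(g)
        assert blocks == []
        assert singles == list(range(5))

    def test_multichromosome_rejected(self, small_panel):
        g, _ = small_panel
        g2 = make_matrix(g.dosages[:, :2], chrom="1")
        bad = make_matrix(np.hstack([g.dosages[:, :1], g2.dosages[:, :1]]))
        bad.variants[1] = type(bad.variants[1])(
            id="other", chrom="21", pos_bp=5, ref_allele="A", alt_allele="G")
        with pytest.raises(ValueError, match="per[- ]chromosome|single chromosome"):
            find_blocks(bad)

    def test_blocks_disjoint_sorted_contiguous(self, small_panel, tight_config):
        g, _ = small_panel
        blocks, singles = find_blocks(g, tight_config)
        covered = []
        for b in blocks:
            assert b.size >= tight_config.min_block_snps
            assert b.end_bp - b.start_bp <= tight_config.max_window_bp
            covered.extend(range(b.first_idx, b.last_idx + 1))
        assert len(covered) == len(set(covered))  # disjoint
        assert covered == sorted(covered)         # position-sorted
        assert set(covered) | set(singles) == set(range(g.n_snps))

    def test_truth_recovery_on_high_ld_panel(self, small_panel):
        g, truth = small_panel
        blocks, _ = find_blocks(g)
        recovered = 0
        for t in truth:
            t_set = set(range(t.first_idx, t.last_idx + 1))
            best = max(
                (len(t_set & set(range(b.first_idx, b.last_idx + 1)))
                 / len(t_set | set(range(b.first_idx, b.last_idx + 1)))
                 for b in blocks), default=0.0)
            recovered += best >= 0.8
        assert recovered >= 0.9 * len(truth) - 1e-9


class TestAveragePairwiseLD:
    def test_duplicated_columns_give_one(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, 200).astype(np.int16)
        g = make_matrix(np.column_stack([col, col, col]))
        blocks, _ = find_blocks(g)
        assert blocks and blocks[0].avg_pairwise_ld == pytest.approx(1.0, abs=1e-6)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        g = make_matrix(rng.binomial(2, 0.4, (10_000, 4)).astype(np.int16))
        from haploae.ld_blocks import Haploblock
        blk = Haploblock("22", 0, 3, 1, 3001, [v.id for v in g.variants])
        assert average_pairwise_ld(g, blk) < 0.05

    def test_two_snp_block_equals_pair_r2(self):
        rng = np.random.default_rng(4)
        dos = correlated_matrix(rng, 300, 2)
        g = make_matrix(dos)
        from haploae import em_haplotype_freqs, ld_statistics
        from haploae.ld_blocks import Haploblock
        p, _ = em_haplotype_freqs(dos[:, 0], dos[:, 1])
        _, _, r2 = ld_statistics(p)
        blk = Haploblock("22", 0, 1, 1, 1001, ["snp0", "snp1"])
        assert average_pairwise_ld(g, blk) == pytest.approx(r2)

    def test_singleton_warns(self, small_panel):
        g, _ = small_panel
        from haploae.ld_blocks import Haploblock
        blk = Haploblock("22", 0, 0, 1, 1, ["b000_s000"])
        with pytest.warns(UserWarning):
            assert np.isnan(average_pairwise_ld(g, blk))


class TestBlockIO:
    def test_round_trip(self, tmp_path, small_panel):
        g, truth = small_panel
        write_blocks(truth, tmp_path / "panel")
        back = read_blocks(tmp_path / "panel.blocks.det", g)
        assert [(b.first_idx, b.last_idx, b.chrom) for b in back] == \
               [(b.first_idx, b.last_idx, b.chrom) for b in truth]

    def test_det_kb_column_matches_definition(self, tmp_path, small_panel):
        g, truth = small_panel
        _, det = write_blocks(truth, tmp_path / "p")
        lines = det.read_text().splitlines()[1:]
        for line, b in zip(lines, truth):
            kb = float(line.split()[3])
            assert kb == pytest.approx((b.end_bp - b.start_bp + 1) / 1000, abs=5e-4)

    def test_unknown_snp_id_raises(self, tmp_path, small_panel):
        g, truth = small_panel
        _, det = write_blocks(truth, tmp_path / "p")
        text = det.read_text().replace("b000_s000", "rs_absent")
        det.write_text(text)
        with pytest.raises(ValueError, match="absent"):
            read_blocks(det, g)
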