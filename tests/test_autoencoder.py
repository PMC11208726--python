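"""Architecture rule, activation, training contracts and metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haploae import (
    ArchitectureSpec,
    BlockSimConfig,
    TrainRecipe,
    build_model,
    compression_ratio,
    encode,
    layer_widths,
    output_activation,
    reconstruct,
    simulate_block,
    snp_accuracy,
    train_block,
)
from haploae.autoencoder import DenseAutoencoder, round_dosage


def oracle_widths(input_dim, hl, bn, p):
    """Independent width computation straight from the taper formula."""
    out = []
    for l in range(-(hl + 1), hl + 2):
        if l == 0:
            out.append(bn)
        elif abs(l) == hl + 1:
            out.append(input_dim)
        else:
            x = bn + (input_dim - bn) * (abs(l) / (hl + 1)) ** p
            out.append(int(math.floor(x + 0.5)))
    return out


WIDTH_CASES = [
    # (input_dim, hl, bn, shape) - includes the reference visualization's
    # inputs=10, hl=4, bn=3 pair
    (10, 4, 3, "elliptic"), (10, 4, 3, "rectangular"),
    (5, 1, 5, "elliptic"), (5, 1, 5, "rectangular"),
    (25, 4, 2, "elliptic"), (25, 4, 3, "elliptic"),
    (25, 4, 2, "rectangular"), (100, 5, 10, "elliptic"),
    (100, 5, 10, "rectangular"), (7, 2, 1, "elliptic"),
    (7, 2, 1, "rectangular"), (50, 3, 5, "elliptic"),
    (50, 3, 5, "rectangular"), (2, 1, 1, "elliptic"),
    (3, 5, 2, "elliptic"), (3, 5, 2, "rectangular"),
    (64, 4, 8, "elliptic"), (64, 4, 8, "rectangular"),
    (33, 2, 4, "elliptic"), (17, 1, 16, "elliptic"),
    (9, 4, 9, "elliptic"), (12, 5, 1, "rectangular"),
]


class TestLayerWidths:
    @pytest.mark.parametrize("input_dim,hl,bn,shape", WIDTH_CASES)
    def test_matches_hand_formula(self, input_dim, hl, bn, shape):
        p = 0.5 if shape == "elliptic" else 0.0
        assert layer_widths(ArchitectureSpec(input_dim, hl, bn, shape)) == \
            oracle_widths(input_dim, hl, bn, p)

    def test_reference_elliptic_example(self):
        assert layer_widths(ArchitectureSpec(10, 4, 3, "elliptic")) == \
            [10, 9, 8, 7, 6, 3, 6, 7, 8, 9, 10]

    def test_rectangular_is_flat(self):
        assert layer_widths(ArchitectureSpec(10, 4, 3, "rectangular")) == \
            [10] * 5 + [3] + [10] * 5

    def test_bn_equal_input_collapses_taper(self):
        assert layer_widths(ArchitectureSpec(5, 1, 5, "elliptic")) == [5] * 5

    @given(
        input_dim=st.integers(2, 200),
        hl=st.integers(1, 6),
        bn_frac=st.floats(0.01, 1.0),
        shape=st.sampled_from(["elliptic", "rectangular"]),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_symmetry_and_monotone_taper(self, input_dim, hl, bn_frac, shape):
        bn = max(1, int(bn_frac * input_dim))
        w = layer_widths(ArchitectureSpec(input_dim, hl, bn, shape))
        assert len(w) == 2 * hl + 3
        assert w == w[::-1]
        assert w[0] == input_dim and w[hl + 1] == bn
        encoder = w[:hl + 2]
        assert all(a >= b for a, b in zip(encoder, encoder[1:]))

    def test_bn_too_large_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(4, 2, 5, "elliptic")


class TestOutputActivation:
    def test_midpoint_and_range(self):
        assert output_activation(np.array(0.0)) == pytest.approx(1.0)
        assert output_activation(np.array(1.0)) == pytest.approx(math.tanh(1) + 1)
        big = output_activation(np.array([8.0, -8.0]))
        assert 0 < big[1] < 1e-6 and 2 - 1e-6 < big[0] < 2

    def test_symmetry(self):
        x = np.linspace(-4, 4, 11)
        np.testing.assert_allclose(output_activation(x) + output_activation(-x), 2.0)


class TestBuildModel:
    def test_parameter_count(self):
        net = DenseAutoencoder([4, 3, 2, 3, 4], seed=0)
        assert net.n_parameters() == (4 * 3 + 3) + (3 * 2 + 2) + (2 * 3 + 3) + (3 * 4 + 4)

    def test_same_seed_bit_identical(self):
        r = TrainRecipe(seed=9)
        a = build_model(ArchitectureSpec(6, 2, 2), r)
        b = build_model(ArchitectureSpec(6, 2, 2), r)
        for wa, wb in zip(a.W, b.W):
            np.testing.assert_array_equal(wa, wb)

    def test_layer_count(self):
        net = build_model(ArchitectureSpec(12, 4, 3), TrainRecipe())
        assert len(net.widths) == 11  # 2*hl + 3


class TestTraining:
    def test_constant_block_reaches_perfect_accuracy(self):
        X = np.tile([0, 1, 2, 1, 0], (120, 1)).astype(np.int16)
        spec = ArchitectureSpec(5, 2, 2)
        m = train_block(spec, X, TrainRecipe(epochs=400, seed=0), block_id="const")
        assert m.val_acc == 1.0

    def test_two_founder_block_compresses_to_one_dimension(self):
        cfg = BlockSimConfig(n_snps=8, n_founders=2, mutation_rate=0.0)
        X, _ = simulate_block(cfg, 800, seed=3)
        spec = ArchitectureSpec(8, 4, 1, "elliptic")
        m = train_block(spec, X, TrainRecipe(epochs=150, seed=0), block_id="k2")
        assert m.val_acc >= 0.99

    def test_loss_decreases_over_training(self):
        cfg = BlockSimConfig(n_snps=10, n_founders=3, mutation_rate=0.01)
        X, _ = simulate_block(cfg, 400, seed=5)
        m = train_block(ArchitectureSpec(10, 4, 3), X, TrainRecipe(seed=1), block_id="b")
        assert m.loss_history[-1] <= m.loss_history[0]

    def test_reconstruction_in_open_interval(self):
        cfg = BlockSimConfig(n_snps=6, n_founders=3, mutation_rate=0.01)
        X, _ = simulate_block(cfg, 200, seed=6)
        m = train_block(ArchitectureSpec(6, 2, 2), X, TrainRecipe(epochs=5, seed=2),
                        block_id="rng")
        rec = reconstruct(m, X)
        assert (rec > 0).all() and (rec < 2).all()
        assert set(np.unique(round_dosage(rec))) <= {0, 1, 2}

    def test_determinism(self):
        cfg = BlockSimConfig(n_snps=6, n_founders=3, mutation_rate=0.01)
        X, _ = simulate_block(cfg, 200, seed=7)
        r = TrainRecipe(epochs=5, seed=4)
        m1 = train_block(ArchitectureSpec(6, 2, 2), X, r, block_id="d")
        m2 = train_block(ArchitectureSpec(6, 2, 2), X, r, block_id="d")
        assert m1.val_mse == m2.val_mse and m1.train_mse == m2.train_mse

    def test_encode_shapes_and_cluster_bound(self):
        K = 4
        cfg = BlockSimConfig(n_snps=12, n_founders=K, mutation_rate=0.0)
        X, _ = simulate_block(cfg, 500, seed=8)
        m = train_block(ArchitectureSpec(12, 4, 2), X, TrainRecipe(epochs=5, seed=0),
                        block_id="emb")
        emb = encode(m, X)
        assert emb.shape == (500, 2)
        # identical rows embed identically: distinct embeddings bounded by
        # the number of founder pairs
        distinct = np.unique(emb.round(9), axis=0)
        assert len(distinct) <= K * (K + 1) // 2

    def test_shape_mismatch_names_block(self):
        X = np.zeros((50, 4), dtype=np.int16)
        m = train_block(ArchitectureSpec(4, 1, 2), X, TrainRecipe(epochs=1, seed=0),
                        block_id="blk42")
        with pytest.raises(ValueError, match="blk42"):
            encode(m, np.zeros((10, 5)))


class TestSnpAccuracy:
    def test_exact_match(self):
        t = np.array([[0, 1], [2, 1]])
        assert snp_accuracy(t.astype(float), t).overall == 1.0

    def test_all_ones_prediction(self):
        truth = np.array([[0, 1, 2]] * 4)
        acc = snp_accuracy(np.ones_like(truth, dtype=float), truth)
        assert acc.overall == pytest.approx(1 / 3)
        assert acc.by_dosage[1] == 1.0 and acc.by_dosage[0] == 0.0

    def test_rounding_boundary_half_up(self):
        truth = np.array([[1, 1, 1]])
        acc = snp_accuracy(np.array([[1.49, 1.51, 1.5]]), truth)
        # 1.49 -> 1 correct; 1.51 -> 2 wrong; 1.5 rounds half-up -> 2 wrong
        assert acc.overall == pytest.approx(1 / 3)

    def test_per_dosage_recombines_to_overall(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 3, (40, 7))
        pred = np.clip(truth + rng.normal(0, 0.6, truth.shape), 1e-6, 2 - 1e-6)
        acc = snp_accuracy(pred, truth)
        total = sum(acc.by_dosage[d] * acc.counts[d] for d in (0, 1, 2))
        assert total / truth.size == pytest.approx(acc.overall)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 3, (30, 5))
        pred = rng.uniform(0.01, 1.99, truth.shape)
        perm = rng.permutation(30)
        assert snp_accuracy(pred, truth).overall == \
            snp_accuracy(pred[perm], truth[perm]).overall


class TestCompressionRatio:
    @pytest.mark.parametrize("bn,dim,expected", [
        (3, 30, 0.10),
        (7341, 70247, 7341 / 70247),
        (5, 5, 1.0),
    ])
    def test_values(self, bn, dim, expected):
        assert compression_ratio(bn, dim) == pytest.approx(expected)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            compression_ratio(0, 10)
        with pytest.raises(ValueError):
            compression_ratio(3, 0)
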