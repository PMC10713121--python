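import numpy as np
import pytest

from haplophase._autodiff import Tensor
from haplophase.corrmodel import (
    CorrelationEncoder,
    EncoderConfig,
    consistency_regularizer,
    contrastive_loss,
    measured_correlations,
    pair_indicator,
    sparsity_regularizer,
    total_loss,
)
from haplophase.fragments import one_hot

from conftest import matrix_from_strings


@pytest.fixture(scope="module")
def tiny_model():
    cfg = EncoderConfig(d_r=8)
    return cfg, CorrelationEncoder(cfg, seq_len=8, rng=0)


def _naive_forward_conv_dense(model, reads):
    """Independent numpy re-implementation of the convolutional embedding."""
    cfg = model.cfg
    x = reads.transpose(0, 2, 1)  # (n, l, C)
    for i, kw in enumerate(cfg.conv_kernels):
        W = model.params[f"conv{i}_W"].data   # (kw, C, Co)
        b = model.params[f"conv{i}_b"].data
        slope = model.params[f"conv{i}_slope"].data
        n, l, C = x.shape
        Co = W.shape[2]
        left = (kw - 1) // 2
        xp = np.pad(x, ((0, 0), (left, kw - 1 - left), (0, 0)))
        out = np.zeros((n, l, Co))
        for ni in range(n):
            for li in range(l):
                for o in range(Co):
                    out[ni, li, o] = b[o] + sum(
                        xp[ni, li + j, c] * W[j, c, o]
                        for j in range(kw) for c in range(C)
                    )
        x = np.where(out > 0, out, slope * out)
    flat = x.reshape(x.shape[0], -1)
    return flat @ model.params["embed_W"].data + model.params["embed_b"].data


class TestEncoder:
    def test_output_shape(self, tiny_model):
        cfg, model = tiny_model
        reads = np.zeros((5, 4, 8))
        reads[:, 0, :] = 1.0
        z = model.encode_reads(reads)
        assert z.shape == (5, cfg.d_r)

    def test_identical_rows_identical_embeddings(self, tiny_model):
        _, model = tiny_model
        m = matrix_from_strings(["ACGTACGT", "ACGTACGT", "TTTTACGT"])
        z = model.encode_reads(one_hot(m)).data
        assert np.allclose(z[0], z[1])
        assert not np.allclose(z[0], z[2])

    def test_conv_dense_chain_matches_naive_oracle(self, tiny_model):
        _, model = tiny_model
        m = matrix_from_strings(["ACGT-CGA"])
        reads = one_hot(m)
        expected = _naive_forward_conv_dense(model, reads)
        got = model.encode_reads(reads).data
        assert np.allclose(got, expected, atol=1e-10)

    def test_too_short_block_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            CorrelationEncoder(EncoderConfig(d_r=8), seq_len=1, rng=0)

    def test_d_q_is_half_d_r(self):
        assert EncoderConfig(d_r=128).d_q == 64
        assert EncoderConfig(d_r=32).d_q == 16

    def test_full_size_defaults(self):
        cfg = EncoderConfig()
        assert cfg.d_r == 128
        assert cfg.conv_filters == (32, 64, 128)
        assert cfg.n_layers == 3 and cfg.n_heads == 4


class TestCorrelationForward:
    def test_unit_diagonal(self, tiny_model):
        _, model = tiny_model
        m = matrix_from_strings(["ACGTACGT", "TGCATGCA", "ACGT----"])
        sigma = model.sigma(one_hot(m))
        assert np.allclose(np.diag(sigma), 1.0, atol=1e-5)

    def test_sigma_matches_independent_gram_product(self, tiny_model):
        _, model = tiny_model
        m = matrix_from_strings(["ACGTACGT", "TGCATGCA", "AAAATTTT"])
        z = model.encode_reads(one_hot(m))
        qn = model.normalized_head(z).data
        sigma = model.sigma(one_hot(m))
        oracle = qn @ qn.T  # independent matrix product
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(sigma[off], oracle[off], atol=1e-12)

    def test_positive_semidefinite(self, tiny_model):
        _, model = tiny_model
        m = matrix_from_strings(["ACGTACGT", "TGCATGCA", "AAAATTTT", "ACGT--GT"])
        sigma = model.sigma(one_hot(m))
        eigs = np.linalg.eigvalsh(sigma)
        assert eigs.min() >= -1e-6

    def test_deterministic_forward(self, tiny_model):
        _, model = tiny_model
        m = matrix_from_strings(["ACGTACGT", "TGCATGCA"])
        s1 = model.sigma(one_hot(m))
        s2 = model.sigma(one_hot(m))
        assert np.abs(s1 - s2).max() < 1e-6

    def test_checkpoint_round_trip(self, tiny_model, tmp_path):
        _, model = tiny_model
        m = matrix_from_strings(["ACGTACGT", "TGCATGCA"])
        path = tmp_path / "model.npz"
        model.save(path)
        clone = CorrelationEncoder.load(path)
        assert np.allclose(model.sigma(one_hot(m)), clone.sigma(one_hot(m)))


class TestMeasuredCorrelations:
    def test_identical_overlap_is_one(self):
        m = matrix_from_strings(["ACGT", "ACGT"])
        assert measured_correlations(m)[0, 1] == 1.0

    def test_disjoint_reads_zero(self):
        m = matrix_from_strings(["AC--", "--GT"])
        assert measured_correlations(m)[0, 1] == 0.0

    def test_three_agree_one_disagree(self):
        m = matrix_from_strings(["ACGT", "ACGA"])
        assert measured_correlations(m)[0, 1] == pytest.approx(0.5)

    def test_symmetric_bounded(self):
        rng = np.random.default_rng(0)
        entries = rng.integers(-1, 4, size=(10, 6)).astype(np.int8)
        from haplophase.fragments import ReadFragmentMatrix
        m = ReadFragmentMatrix(entries, [f"r{i}" for i in range(10)], np.arange(6))
        C = measured_correlations(m)
        assert np.allclose(C, C.T)
        assert C.min() >= -1.0 and C.max() <= 1.0

    def test_full_disagreement_is_minus_one(self):
        m = matrix_from_strings(["ACGT", "TGCA"])
        assert measured_correlations(m)[0, 1] == -1.0


class TestLosses:
    def test_contrastive_zero_at_ideal(self):
        p = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
        sigma = np.array([[1, 1, -1], [1, 1, -1], [-1, -1, 1]], dtype=float)
        assert contrastive_loss(sigma, p) == 0.0

    def test_contrastive_single_pair(self):
        p = np.ones((2, 2))
        sigma = np.eye(2)
        assert contrastive_loss(sigma, p) == pytest.approx(1.0)  # (1-0)^2

    def test_contrastive_three_pairs(self):
        p = np.eye(3)
        p[0, 1] = p[1, 0] = 1.0
        sigma = np.eye(3)
        assert contrastive_loss(sigma, p) == pytest.approx(3.0)

    def test_consistency_zero_on_support(self):
        c = np.array([[1, 0.5], [0.5, 1]])
        assert consistency_regularizer(c.copy(), c) == pytest.approx(0.0, abs=1e-9)

    def test_consistency_single_pair_norm(self):
        c = np.array([[1, 0.25, 0], [0.25, 1, 0], [0, 0, 1]])
        sigma = c.copy()
        sigma[0, 1] = sigma[1, 0] = 0.75  # difference 0.5 in both entries
        assert consistency_regularizer(sigma, c) == pytest.approx(np.sqrt(0.5), rel=1e-6)

    def test_consistency_ignores_unsupported_entries(self):
        c = np.array([[1, 0.25, 0], [0.25, 1, 0], [0, 0, 1]])
        s1 = c.copy()
        s2 = c.copy()
        s2[0, 2] = s2[2, 0] = 0.9  # C is zero there: must not contribute
        assert consistency_regularizer(s1, c) == consistency_regularizer(s2, c)

    def test_sparsity_zero_for_diagonal(self):
        assert sparsity_regularizer(np.eye(4)) == 0.0

    def test_sparsity_counts_both_orderings(self):
        sigma = np.full((3, 3), 0.5)
        np.fill_diagonal(sigma, 1.0)
        assert sparsity_regularizer(sigma) == pytest.approx(3.0)

    def test_sparsity_monotone(self):
        rng = np.random.default_rng(0)
        sigma = rng.uniform(-1, 1, size=(5, 5))
        bigger = np.sign(sigma) * np.minimum(np.abs(sigma) * 1.5, 1.0)
        np.fill_diagonal(bigger, np.diag(sigma))
        assert sparsity_regularizer(bigger) >= sparsity_regularizer(sigma)

    def test_total_loss_weights(self):
        sigma = np.eye(2)
        c = np.zeros((2, 2))
        p = np.ones((2, 2))
        lc = contrastive_loss(sigma, p)
        assert lc == pytest.approx(1.0)
        # verify linear combination on arbitrary components
        val = total_loss(sigma, c, p, lambda_r=100.0, lambda_s=10.0)
        expected = (contrastive_loss(sigma, p)
                    + 100.0 * consistency_regularizer(sigma, c)
                    + 10.0 * sparsity_regularizer(sigma))
        assert val == pytest.approx(expected)

    def test_total_loss_reduces_to_contrastive(self):
        rng = np.random.default_rng(1)
        sigma = rng.uniform(-1, 1, size=(4, 4))
        c = rng.uniform(-1, 1, size=(4, 4))
        p = (rng.random((4, 4)) < 0.5).astype(float)
        assert total_loss(sigma, c, p, 0.0, 0.0) == pytest.approx(
            contrastive_loss(sigma, p))


class TestGradients:
    def test_finite_difference_gradient_check(self):
        """Backpropagated gradients match central differences to <1e-3."""
        cfg = EncoderConfig(d_r=8)
        model = CorrelationEncoder(cfg, seq_len=6, rng=3)
        m = matrix_from_strings(["ACGTAC", "TGCATG", "ACG-AC", "TG-ATG"])
        reads = one_hot(m)
        C = measured_correlations(m)
        p = pair_indicator(np.array([0, 1, 0, 1]))

        def loss_value():
            return total_loss(model.forward(reads), C, p).item()

        L = total_loss(model.forward(reads), C, p)
        for t in model.parameters():
            t.grad = None
        L.backward()
        rng = np.random.default_rng(0)
        eps = 1e-6
        for name in ["conv0_W", "conv1_slope", "embed_W", "te0_Wq",
                     "te1_ffn_W1", "te2_ln2_g", "head_W"]:
            t = model.params[name]
            flat_idx = rng.integers(0, t.data.size)
            idx = np.unravel_index(flat_idx, t.data.shape)
            old = t.data[idx]
            t.data[idx] = old + eps
            up = loss_value()
            t.data[idx] = old - eps
            down = loss_value()
            t.data[idx] = old
            numeric = (up - down) / (2 * eps)
            analytic = t.grad[idx]
            denom = max(abs(numeric), abs(analytic), 1e-8)
            assert abs(numeric - analytic) / denom < 1e-3, name
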