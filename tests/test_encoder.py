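import numpy as np
import pytest

import phyloquartet as pq
from phyloquartet.encoder import SequenceEncoder


class TestOneHotEncode:
    def test_acgt_identity(self):
        enc = pq.one_hot_encode("ACGT")
        assert np.array_equal(enc.matrix, np.eye(4))

    def test_case_and_rna_normalization(self):
        assert np.array_equal(
            pq.one_hot_encode("acgu").matrix, pq.one_hot_encode("ACGT").matrix
        )

    def test_ambiguous_and_gap_columns_zero(self):
        enc = pq.one_hot_encode("ANT-")
        assert enc.matrix[:, 1].sum() == 0
        assert enc.matrix[:, 3].sum() == 0
        assert enc.matrix[:, 0].sum() == 1

    def test_invalid_character_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            pq.one_hot_encode("ACXT")

    def test_batch_requires_equal_lengths(self):
        with pytest.raises(ValueError, match="unequal"):
            pq.encode_batch({"a": "ACGT", "b": "ACG"})


class TestBuildEncoder:
    @pytest.mark.parametrize("L", [350, 35])
    def test_output_dimension(self, L):
        model = pq.build_encoder(L, latent_dim=30, seed=0)
        X = np.zeros((2, 4, L))
        out = model.forward(X)
        assert out.shape == (2, 30)

    def test_valid_convolution_geometry(self):
        model = pq.build_encoder(350, seed=0)
        assert model.conv_positions == 341
        assert model.pooled == 68

    def test_deterministic_initialization(self):
        a = pq.build_encoder(35, seed=4)
        b = pq.build_encoder(35, seed=4)
        for key in a.params:
            assert np.array_equal(a.params[key], b.params[key])
        c = pq.build_encoder(35, seed=5)
        assert any(not np.array_equal(a.params[k], c.params[k]) for k in a.params)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            pq.build_encoder(9, seed=0)

    def test_extra_hidden_variant(self):
        model = pq.build_encoder(35, seed=0, extra_hidden=True)
        assert "W2" in model.params
        out = model.forward(np.zeros((1, 4, 35)))
        assert out.shape == (1, 30)


class TestEmbed:
    def test_identical_sequences_identical_rows(self, study_alignment):
        model = pq.build_encoder(35, seed=1)
        seqs = dict(study_alignment.sequences)
        taxa = sorted(seqs)
        seqs[taxa[1]] = seqs[taxa[0]]
        F = pq.embed(model, seqs)
        assert np.array_equal(F.vectors[0], F.vectors[1])
        D = pq.latent_distances(F)
        assert D[0, 1] == 0.0

    def test_untrained_embedding_shape_and_range(self, study_alignment):
        model = pq.build_encoder(35, seed=1)
        F = pq.embed(model, study_alignment.sequences)
        assert F.vectors.shape == (13, 30)
        assert np.isfinite(F.vectors).all()
        assert (F.vectors >= 0.0).all()  # final ReLU

    def test_row_order_is_canonical(self, study_alignment):
        model = pq.build_encoder(35, seed=1)
        seqs = study_alignment.sequences
        reversed_insertion = dict(sorted(seqs.items(), reverse=True))
        F1 = pq.embed(model, seqs)
        F2 = pq.embed(model, reversed_insertion)
        assert F1.taxa == F2.taxa == tuple(sorted(seqs))
        assert np.array_equal(F1.vectors, F2.vectors)

    def test_length_mismatch(self, study_alignment):
        model = pq.build_encoder(40, seed=1)
        with pytest.raises(ValueError, match="length"):
            pq.embed(model, study_alignment.sequences)

    def test_dropout_only_in_training_mode(self):
        model = pq.build_encoder(35, seed=0)
        X = np.random.default_rng(0).random((3, 4, 35))
        a = model.forward(X)
        b = model.forward(X)
        assert np.array_equal(a, b)
        rng = np.random.default_rng(1)
        c = model.forward(X, train=True, rng=rng)
        d = model.forward(X, train=True, rng=rng)
        assert not np.array_equal(c, d)


class TestLatentDistances:
    def test_three_four_five(self):
        F = pq.FeatureMatrix(np.array([[0.0, 0.0], [3.0, 4.0]]), ("a", "b"))
        D = pq.latent_distances(F)
        assert D[0, 1] == pytest.approx(5.0)

    def test_matches_loop_oracle(self, rng):
        V = rng.random((6, 5))
        D = pq.pairwise_distances(V)
        for i in range(6):
            for j in range(6):
                assert D[i, j] == pytest.approx(
                    np.sqrt(((V[i] - V[j]) ** 2).sum())
                )

    def test_triangle_inequality(self, rng):
        for _ in range(20):
            V = rng.random((8, 4)) * 10
            D = pq.pairwise_distances(V)
            for i in range(8):
                for j in range(8):
                    for k in range(8):
                        assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


class TestBackward:
    def test_gradient_flow(self, study_alignment):
        """At random init, backprop reaches every parameter tensor."""
        model = pq.build_encoder(35, seed=2)
        X, _ = pq.encode_batch(study_alignment.sequences)
        F, cache = model.forward(X, want_cache=True)
        grads = model.backward(cache, np.ones_like(F))
        assert set(grads) == set(model.params)
        assert any(np.abs(g).max() > 0 for g in grads.values())

    def test_matches_finite_differences(self):
        model = SequenceEncoder(
            length=12, latent_dim=3, n_filters=2, kernel_size=4,
            pool_size=2, hidden=5, dropout=0.0, seed=3,
        )
        rng = np.random.default_rng(0)
        X = rng.random((3, 4, 12))
        w = rng.standard_normal(3)  # random linear readout

        def scalar_loss():
            return float(model.forward(X) @ w @ np.ones(3))

        F, cache = model.forward(X, want_cache=True)
        dF = np.tile(w, (3, 1))
        grads = model.backward(cache, dF)
        h = 1e-6
        for key, P in model.params.items():
            flat = P.ravel()
            for idx in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[idx]
                flat[idx] = orig + h
                up = scalar_loss()
                flat[idx] = orig - h
                down = scalar_loss()
                flat[idx] = orig
                fd = (up - down) / (2 * h)
                assert grads[key].ravel()[idx] == pytest.approx(fd, abs=1e-5, rel=1e-4), key


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path, study_alignment):
        model = pq.build_encoder(35, seed=6)
        path = tmp_path / "model.npz"
        pq.save_model(model, path)
        loaded = pq.load_model(path)
        assert loaded.config() == model.config()
        X, _ = pq.encode_batch(study_alignment.sequences)
        assert np.array_equal(model.forward(X), loaded.forward(X))


class TestFasta:
    def test_roundtrip(self, tmp_path, study_alignment):
        path = tmp_path / "seqs.fasta"
        pq.write_fasta(study_alignment.sequences, path)
        back = pq.read_fasta(path)
        assert back == study_alignment.sequences

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError):
            pq.read_fasta(path)
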