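import numpy as np
import pytest

from mdfuse import (
    GCNEncoder,
    MultiScaleCNN,
    atom_features,
    encode_sequence_tokens,
    normalize_adjacency,
    smiles_to_graph,
)
from mdfuse.intrinsic_encoders import (
    MolecularGraph,
    N_ATOM_FEATURES,
    PAD_INDEX,
    SmilesParseError,
)
from mdfuse.synthetic import SyntheticSpec, generate_drugs


class TestSequenceTokens:
    def test_short_sequence_padded_at_three_prime_end(self):
        p = encode_sequence_tokens("ACGU" * 5)  # 20 nt
        assert p.mask.sum() == 20
        assert np.all(p.token_indices[20:] == PAD_INDEX)
        assert np.all(p.mask[:20]) and not np.any(p.mask[20:])

    def test_exact_length_unchanged(self):
        p = encode_sequence_tokens("ACGU" * 6)  # 24 nt
        assert p.mask.all()
        assert np.array_equal(p.token_indices[:4], [0, 1, 2, 3])

    def test_long_sequence_keeps_five_prime_prefix(self):
        seq = "A" * 10 + "C" * 20  # 30 nt
        p = encode_sequence_tokens(seq)
        assert p.mask.all()
        assert np.all(p.token_indices[:10] == 0)
        assert np.all(p.token_indices[10:] == 1)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            encode_sequence_tokens("")


class TestNormalizeAdjacency:
    def test_single_node(self):
        np.testing.assert_array_equal(normalize_adjacency(np.zeros((1, 1))),
                                      [[1.0]])

    def test_two_node_edge_all_entries_half(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(normalize_adjacency(A), np.full((2, 2), 0.5))

    def test_three_node_path_hand_values(self):
        # path a-b-c: degrees with self-loops (2, 3, 2)
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        A[1, 2] = A[2, 1] = 1.0
        Ahat = normalize_adjacency(A)
        assert Ahat[0, 0] == pytest.approx(1 / 2)
        assert Ahat[0, 1] == pytest.approx(1 / np.sqrt(6))
        assert Ahat[1, 1] == pytest.approx(1 / 3)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(25):
            n = rng.integers(1, 9)
            A = np.triu(rng.random((n, n)) < 0.4, k=1).astype(float)
            A = A + A.T
            got = normalize_adjacency(A)
            AI = A + np.eye(n)
            deg = AI.sum(axis=1)
            expected = np.zeros((n, n))
            for i in range(n):
                for j in range(n):
                    expected[i, j] = AI[i, j] / np.sqrt(deg[i] * deg[j])
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_asymmetric_rejected(self):
        A = np.array([[0.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            normalize_adjacency(A)


class TestSmilesToGraph:
    def test_ethane(self):
        g = smiles_to_graph("CC")
        assert g.n_atoms == 2 and g.edges == [(0, 1)]

    def test_cyclopropane(self):
        g = smiles_to_graph("C1CC1")
        assert g.n_atoms == 3 and len(g.edges) == 3

    def test_parse_error_carries_drug_id(self):
        with pytest.raises(SmilesParseError, match="drug-x"):
            smiles_to_graph("C(", drug_id="drug-x")


class TestAtomFeatures:
    def test_ethane_carbon_slots(self):
        g = smiles_to_graph("CC")
        f = g.atom_feats[0]
        assert f.shape == (N_ATOM_FEATURES,)
        assert f[0] == 1.0  # atom type C is slot 0
        # degree block starts after type (10) + hybridization (4): degree 1
        assert f[10 + 4 + 1] == 1.0
        # formal charge 0 (slot index 2 in [-2..2]) after degree block (7)
        assert f[10 + 4 + 7 + 2] == 1.0
        # 3 implicit hydrogens
        assert f[10 + 4 + 7 + 6 + 3] == 1.0

    def test_symmetric_atoms_identical(self):
        g = smiles_to_graph("CC")
        np.testing.assert_array_equal(g.atom_feats[0], g.atom_feats[1])

    def test_ammonium_charge_slot(self):
        g = smiles_to_graph("[NH4+]")
        f = g.atom_feats[0]
        assert f[1] == 1.0  # N
        assert f[10 + 4 + 7 + 3] == 1.0  # formal charge +1
        assert f[10 + 4 + 7 + 6 + 4] == 1.0  # four hydrogens


class TestMultiScaleCNN:
    def _oracle(self, cnn, tokens, mask):
        """Per-window loop re-implementation of the branch computation."""
        emb = cnn.embedding.data
        outs = []
        for n in range(tokens.shape[0]):
            x = emb[tokens[n]] * mask[n][:, None]
            branch_maxes = []
            for k in cnn.kernel_sizes:
                best = None
                for j in range(tokens.shape[1] - k + 1):
                    if not mask[n, j]:
                        continue  # window entirely in padding
                    window = x[j:j + k].reshape(-1)
                    val = np.maximum(window @ cnn.conv_w[k].data
                                     + cnn.conv_b[k].data, 0.0)
                    best = val if best is None else np.maximum(best, val)
                branch_maxes.append(best)
            z = np.concatenate(branch_maxes)
            outs.append(np.maximum(z @ cnn.W_out.data + cnn.b_out.data, 0.0))
        return np.stack(outs)

    def test_matches_per_window_loop_oracle(self, rng):
        cnn = MultiScaleCNN(d_out=12, rng=rng, embed_dim=6, channels=5)
        tokens = rng.integers(0, 4, size=(8, 24))
        lengths = rng.integers(18, 25, size=8)
        mask = np.arange(24)[None, :] < lengths[:, None]
        tokens[~mask] = PAD_INDEX
        got = cnn(tokens, mask).data
        np.testing.assert_allclose(got, self._oracle(cnn, tokens, mask),
                                   atol=1e-10)

    def test_output_width_is_dm(self, rng):
        cnn = MultiScaleCNN(d_out=128, rng=rng)
        tokens = rng.integers(0, 4, size=(3, 24))
        mask = np.ones((3, 24), dtype=bool)
        assert cnn(tokens, mask).data.shape == (3, 128)

    def test_zero_conv_weights_pool_to_bias_activation(self, rng):
        cnn = MultiScaleCNN(d_out=7, rng=rng, embed_dim=4, channels=3)
        for k in cnn.kernel_sizes:
            cnn.conv_w[k].data[:] = 0.0
            cnn.conv_b[k].data[:] = np.array([0.5, -1.0, 2.0])
        tokens = rng.integers(0, 4, size=(2, 24))
        mask = np.ones((2, 24), dtype=bool)
        z = np.tile(np.maximum([0.5, -1.0, 2.0], 0.0), len(cnn.kernel_sizes))
        expected = np.maximum(z @ cnn.W_out.data + cnn.b_out.data, 0.0)
        np.testing.assert_allclose(cnn(tokens, mask).data,
                                   np.stack([expected, expected]), atol=1e-12)

    def test_output_independent_of_pad_embedding_row(self, rng):
        cnn = MultiScaleCNN(d_out=9, rng=rng, embed_dim=5, channels=4)
        p = encode_sequence_tokens("ACGU" * 5)  # padded sequence
        tokens = p.token_indices[None, :]
        mask = p.mask[None, :]
        out1 = cnn(tokens, mask).data
        cnn.embedding.data[PAD_INDEX] += 100.0  # pad row must be inert
        out2 = cnn(tokens, mask).data
        np.testing.assert_array_equal(out1, out2)

    def test_kernel_exceeding_max_len_rejected(self, rng):
        with pytest.raises(ValueError, match="kernel"):
            MultiScaleCNN(d_out=8, rng=rng, kernel_sizes=(30,))


class TestGCNEncoder:
    def test_single_atom_readout_is_twice_final_vector(self, rng):
        g = smiles_to_graph("C")
        enc = GCNEncoder(N_ATOM_FEATURES, rng, widths=(8, 8, 8))
        h = g.atom_feats
        for w in enc.weights:
            h = np.maximum(h @ w.data, 0.0)  # Ahat = [[1]]
        np.testing.assert_allclose(enc.encode_one(g).data, 2.0 * h[0],
                                   atol=1e-12)

    def test_permutation_invariance_on_synthetic_molecules(self, rng):
        drugs = generate_drugs(SyntheticSpec(n_drugs=24, seed=5))
        enc = GCNEncoder(N_ATOM_FEATURES, rng, widths=(16, 16, 16))
        for d in drugs:
            g = smiles_to_graph(d.smiles)
            perm = rng.permutation(g.n_atoms)
            gp = MolecularGraph(
                atom_feats=g.atom_feats[perm],
                edges=g.edges,
                adjacency=g.adjacency[np.ix_(perm, perm)])
            np.testing.assert_allclose(enc.encode_one(g).data,
                                       enc.encode_one(gp).data, atol=1e-5)

    def test_zero_weights_give_zero_readout(self, rng):
        enc = GCNEncoder(N_ATOM_FEATURES, rng, widths=(8, 8, 8))
        for w in enc.weights:
            w.data[:] = 0.0
        g = smiles_to_graph("CCO")
        np.testing.assert_array_equal(enc.encode_one(g).data, np.zeros(8))

    def test_feature_width_mismatch_errors(self, rng):
        enc = GCNEncoder(10, rng, widths=(4, 4, 4))
        with pytest.raises(ValueError, match="width"):
            enc.encode_one(smiles_to_graph("CC"))
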