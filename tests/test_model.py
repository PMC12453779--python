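"""Network components: positional encoding, GCN propagation, attention
identities, CP-Encoder structure, cross-fusion wiring, ablations and
forward-pass contracts."""

import math

import numpy as np
import pytest

from dtafusion.exceptions import ConfigError
from dtafusion.model import (
    AffinityNet,
    ModelConfig,
    QKVMode,
    collate,
    gcn_layer,
    mol_graph_from_smiles,
    positional_encoding,
)
from dtafusion.nn.autodiff import Tensor
from dtafusion.nn.layers import (
    EncoderLayer, MultiHeadAttention, scaled_dot_attention,
)
from dtafusion.presets import desk_config


class TestPositionalEncoding:
    def test_first_two_columns_are_sin_cos_of_position(self):
        pe = positional_encoding(5, 8)
        for r in range(5):
            i = r + 1  # positions indexed from 1
            assert pe[r, 0] == pytest.approx(math.sin(i))
            assert pe[r, 1] == pytest.approx(math.cos(i))

    def test_spot_check_row2_col2_t4(self):
        pe = positional_encoding(3, 4)
        # position i = 2, j = 1 pair -> sin(2 / 10000^(2/4)) = sin(0.02)
        assert pe[1, 2] == pytest.approx(math.sin(2.0 / 100.0))
        assert pe[1, 3] == pytest.approx(math.cos(2.0 / 100.0))

    def test_entries_bounded(self):
        pe = positional_encoding(50, 16)
        assert np.all(pe <= 1.0) and np.all(pe >= -1.0)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ConfigError):
            positional_encoding(4, 7)


class TestGCNLayer:
    def test_single_node_identity_weight_is_relu(self):
        x = np.array([[1.5, -2.0, 0.5]])
        out = gcn_layer(x, np.ones((1, 1)), np.eye(3))
        np.testing.assert_allclose(out, [[1.5, 0.0, 0.5]])

    def test_disconnected_nodes_stay_independent(self, rng):
        X = rng.normal(size=(2, 3))
        A_tilde = np.eye(2)  # two isolated nodes with self-loops
        W = rng.normal(size=(3, 3))
        out = gcn_layer(X, A_tilde, W)
        out0 = gcn_layer(X[:1], np.ones((1, 1)), W)
        np.testing.assert_allclose(out[0], out0[0], atol=1e-12)

    def test_matches_dense_bruteforce(self, rng):
        A = (rng.random((5, 5)) > 0.5).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        X = rng.normal(size=(5, 4))
        W = rng.normal(size=(4, 6))
        A_tilde = A + np.eye(5)
        D = np.diag(A_tilde.sum(1))
        D_inv_sqrt = np.linalg.inv(np.sqrt(D))
        expected = np.maximum(D_inv_sqrt @ A_tilde @ D_inv_sqrt @ X @ W, 0.0)
        np.testing.assert_allclose(gcn_layer(X, A_tilde, W), expected,
                                   atol=1e-6)


class TestAttentionIdentities:
    def test_single_key_returns_value_row(self, rng):
        Q = Tensor(rng.normal(size=(3, 4)))
        K = Tensor(rng.normal(size=(1, 4)))
        V = Tensor(rng.normal(size=(1, 4)))
        out = scaled_dot_attention(Q, K, V)
        np.testing.assert_allclose(out.data, np.repeat(V.data, 3, axis=0),
                                   atol=1e-12)

    def test_weight_rows_sum_to_one(self, rng):
        out, w = scaled_dot_attention(
            Tensor(rng.normal(size=(4, 8))), Tensor(rng.normal(size=(6, 8))),
            Tensor(rng.normal(size=(6, 8))), return_weights=True)
        np.testing.assert_allclose(w.data.sum(-1), 1.0, atol=1e-6)

    def test_two_key_hand_case(self):
        Q = Tensor(np.array([[1.0, 0.0]]))
        K = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
        V = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
        out = scaled_dot_attention(Q, K, V)
        z = 1.0 / math.sqrt(2.0)
        w1 = math.exp(z) / (math.exp(z) + 1.0)
        np.testing.assert_allclose(out.data, [[w1, 1.0 - w1]], atol=1e-12)

    def test_multihead_single_head_identity_projections(self, rng):
        mha = MultiHeadAttention(4, 1, np.random.default_rng(0))
        for lin in (mha.Wq, mha.Wk, mha.Wv, mha.Wo):
            lin.W.data = np.eye(4)
        x = Tensor(rng.normal(size=(1, 5, 4)))
        out = mha(x, x, x)
        ref = scaled_dot_attention(Tensor(x.data), Tensor(x.data),
                                   Tensor(x.data))
        np.testing.assert_allclose(out.data, ref.data, atol=1e-10)

    def test_permuting_keys_and_values_together_is_invariant(self, rng):
        mha = MultiHeadAttention(8, 4, np.random.default_rng(1))
        q = Tensor(rng.normal(size=(1, 3, 8)))
        kv = rng.normal(size=(1, 6, 8))
        perm = np.random.default_rng(2).permutation(6)
        out1 = mha(q, Tensor(kv), Tensor(kv))
        out2 = mha(q, Tensor(kv[:, perm]), Tensor(kv[:, perm]))
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-10)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError):
            MultiHeadAttention(10, 4, np.random.default_rng(0))


class TestCPEncoder:
    def _net(self, **kw):
        return AffinityNet(desk_config(seed=3, **kw))

    def test_output_shape_is_length_by_t(self):
        net = self._net()
        tokens = np.array([[1, 2, 3, 0, 0]])
        mask = np.array([[True, True, True, False, False]])
        out = net.encode_drug_seq(tokens, mask)
        assert out.shape == (1, 5, 16)

    def test_all_pad_input_is_finite(self):
        net = self._net()
        tokens = np.zeros((1, 4), dtype=np.int64)
        mask = np.zeros((1, 4), dtype=bool)
        out = net.encode_drug_seq(tokens, mask)
        assert np.all(np.isfinite(out.data))

    def test_zeroed_parallel_projections_reduce_to_first_encoder_plus_input(self):
        net = self._net()
        enc = net.drug_encoder
        enc.out2.W.data = np.zeros_like(enc.out2.W.data)
        enc.out3.W.data = np.zeros_like(enc.out3.W.data)
        tokens = np.array([[1, 2, 3]])
        mask = np.ones((1, 3), dtype=bool)
        X = net.drug_embed(tokens) + Tensor(net.pe_drug[:3])
        expected = enc.enc1(X, key_mask=mask) + X
        out = net.encode_drug_seq(tokens, mask)
        np.testing.assert_allclose(out.data, expected.data, atol=1e-6)

    def test_plain_encoder_when_cp_disabled(self):
        net = self._net(use_cp_encoder=False)
        assert isinstance(net.drug_encoder, EncoderLayer)

    def test_pad_content_never_changes_output(self, small_dataset, small_cfg):
        """Masking contract: rewriting pad positions leaves outputs bitwise
        unchanged."""
        d, p, _ = small_dataset.subset_arrays(np.arange(3))
        net = AffinityNet(small_cfg)
        batch1 = collate(d, p, small_cfg)
        out1 = net.forward(batch1).numpy().copy()
        batch2 = collate(d, p, small_cfg)
        toks = batch2.prot_tokens.copy()
        toks[~batch2.prot_mask] = 7  # arbitrary real token id in pad slots
        batch2.prot_tokens = toks
        out2 = net.forward(batch2).numpy()
        np.testing.assert_array_equal(out1, out2)


class TestMolGraph:
    def test_benzene_graph(self):
        g = mol_graph_from_smiles("c1ccccc1")
        assert g.n_nodes == 6
        assert g.adjacency.sum() == 12  # six aromatic bonds, symmetric
        assert np.all(g.node_features[:, -1] == 1.0)  # aromatic flags

    def test_invalid_smiles_rejected(self):
        with pytest.raises(ValueError):
            mol_graph_from_smiles("xx((")


class TestForwardContracts:
    def test_branch_concatenation_is_512(self, small_dataset, small_cfg):
        net = AffinityNet(small_cfg)
        assert net.fc1.W.shape == (512, 2048)
        assert net.fc2.W.shape == (2048, 768)
        assert net.out.W.shape == (768, 1)

    def test_zero_initialized_head_outputs_zero(self, small_dataset, small_cfg):
        net = AffinityNet(small_cfg)
        net.out.W.data = np.zeros_like(net.out.W.data)
        net.out.b.data = np.zeros_like(net.out.b.data)
        d, p, _ = small_dataset.subset_arrays(np.arange(4))
        out = net.forward(collate(d, p, small_cfg))
        np.testing.assert_array_equal(out.data, np.zeros(4))

    def test_batched_equals_per_pair(self, small_dataset, small_cfg):
        net = AffinityNet(small_cfg)
        d, p, _ = small_dataset.subset_arrays(np.arange(6))
        batched = net.predict(d, p)
        singles = np.array([net.predict([di], [pi])[0]
                            for di, pi in zip(d, p)])
        np.testing.assert_allclose(batched, singles, atol=1e-6)

    def test_fixed_seed_forward_is_bit_reproducible(self, small_dataset,
                                                    small_cfg):
        d, p, _ = small_dataset.subset_arrays(np.arange(4))
        out1 = AffinityNet(small_cfg).predict(d, p)
        out2 = AffinityNet(small_cfg).predict(d, p)
        np.testing.assert_array_equal(out1, out2)

    def test_atom_permutation_invariance_of_fused_branch(self, small_dataset,
                                                         small_cfg):
        """With the physicochemical query attending over the atom set, the
        drug fusion output must not depend on atom order."""
        from dtafusion.model import MolGraph
        from dtafusion.model import DrugRecord

        d, p, _ = small_dataset.subset_arrays(np.arange(2))
        net = AffinityNet(small_cfg)
        out1 = net.predict(d, p)
        perm_drugs = []
        rng = np.random.default_rng(0)
        for rec in d:
            g = rec.graph
            perm = rng.permutation(g.n_nodes)
            g2 = MolGraph(g.node_features[perm],
                          g.adjacency[np.ix_(perm, perm)])
            perm_drugs.append(DrugRecord(rec.drug_id, rec.smiles, rec.tokens,
                                         g2, rec.pc_vector))
        out2 = net.predict(perm_drugs, p)
        np.testing.assert_allclose(out1, out2, atol=1e-5)  # float32 resummation

    def test_table6_qkv_mode_runs_and_differs(self, small_dataset):
        cfg_a = desk_config(seed=3)
        cfg_b = desk_config(seed=3, qkv_mode="table6_best")
        d, p, _ = small_dataset.subset_arrays(np.arange(3))
        out_a = AffinityNet(cfg_a).predict(d, p)
        out_b = AffinityNet(cfg_b).predict(d, p)
        assert out_a.shape == out_b.shape == (3,)
        assert not np.allclose(out_a, out_b)


class TestAblations:
    FLAGS = ("use_drug_pc", "use_protein_pc", "use_mcat", "use_gnn",
             "use_cp_encoder", "use_curvature", "use_potential")

    @pytest.mark.parametrize("flag", FLAGS)
    def test_parameter_count_strictly_decreases(self, flag):
        full = AffinityNet(ModelConfig(seed=0)).n_parameters()
        ablated = AffinityNet(ModelConfig(seed=0, **{flag: False})).n_parameters()
        assert ablated < full

    @pytest.mark.parametrize("flag", FLAGS)
    def test_ablated_forward_still_works(self, flag, small_dataset):
        cfg = desk_config(seed=3, **{flag: False})
        d, p, _ = small_dataset.subset_arrays(np.arange(2))
        out = AffinityNet(cfg).predict(d, p)
        assert out.shape == (2,) and np.all(np.isfinite(out))

    def test_protein_pc_ablation_removes_pc_projection(self):
        cfg = desk_config(seed=0, use_protein_pc=False)
        net = AffinityNet(cfg)
        assert not hasattr(net, "prot_pc_proj")
        assert not hasattr(net, "cross_prot")

    def test_config_invariants_enforced(self):
        with pytest.raises(ConfigError):
            ModelConfig(branch_dim=64)
        with pytest.raises(ConfigError):
            ModelConfig(embed_dim=30, n_heads=4)
        with pytest.raises(ConfigError):
            ModelConfig.from_dict({"embed_dim": 16, "bogus_key": 1})
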