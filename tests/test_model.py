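import numpy as np
import pytest

from cpinet.autodiff import Tensor
from cpinet.model import (CPIModel, ModelConfig, PairwiseInteractionLabel,
                          pim_from_sparse)

from conftest import zero_parameters
from test_graph_encoder import permute_graph


def _forward(model, record, proteins, capture=None):
    return model.forward(record, proteins[record.protein_id], capture)


class TestSiteHead:
    def test_zero_weights_give_half_everywhere(self, micro_model):
        zero_parameters(micro_model)
        probs = micro_model.predict_sites(Tensor(np.ones((3, 4))),
                                          Tensor(np.ones((5, 4))))
        np.testing.assert_allclose(probs.data, 0.5)
        assert probs.shape == (3, 5)

    def test_hand_computed_two_by_two(self, micro_model):
        m = CPIModel(ModelConfig(d0=6, d1=2, n_conv_layers=1, gnn_layers=1,
                                 kernel_size=3))
        m.site_fc_atom.weight.data = np.array([[1.0, 0.0], [0.0, 1.0]])
        m.site_fc_atom.bias.data[:] = 0
        m.site_fc_res.weight.data = np.array([[2.0, 0.0], [0.0, 0.5]])
        m.site_fc_res.bias.data[:] = 0
        atoms = np.array([[1.0, 2.0], [0.5, -1.0]])
        res = np.array([[1.0, 1.0], [-1.0, 2.0]])
        probs = m.predict_sites(Tensor(atoms), Tensor(res)).data
        # fc_c = atoms, fc_p = res * [2, .5]; entry = sigmoid(dot)
        expected = 1 / (1 + np.exp(-(atoms @ (res * [2.0, 0.5]).T)))
        np.testing.assert_allclose(probs, expected, atol=1e-12)

    def test_width_mismatch_errors(self, micro_model):
        with pytest.raises(ValueError, match="width"):
            micro_model.predict_sites(Tensor(np.ones((2, 4))),
                                      Tensor(np.ones((2, 3))))


class TestDualAttention:
    def test_identical_atoms_give_uniform_weights(self, micro_model, rng):
        atom = rng.standard_normal(4)
        atoms = Tensor(np.tile(atom, (5, 1)))
        res = Tensor(rng.standard_normal((3, 4)))
        c_ctx, p_ctx = micro_model.dual_attention(atoms, res)
        np.testing.assert_allclose(c_ctx.data[0], atom, atol=1e-10)

    def test_single_atom_single_residue_contexts(self, micro_model, rng):
        a = rng.standard_normal((1, 4))
        r = rng.standard_normal((1, 4))
        c_ctx, p_ctx = micro_model.dual_attention(Tensor(a), Tensor(r))
        np.testing.assert_allclose(c_ctx.data, a, atol=1e-12)
        np.testing.assert_allclose(p_ctx.data, r, atol=1e-12)

    def test_matches_double_loop_oracle(self, micro_model, rng):
        atoms = rng.standard_normal((3, 4))
        res = rng.standard_normal((4, 4))
        c_ctx, p_ctx = micro_model.dual_attention(Tensor(atoms), Tensor(res))
        W = micro_model.att_weight.data
        A = np.tanh(atoms @ W @ res.T)
        aw = np.exp(A.max(axis=1)); aw /= aw.sum()
        rw = np.exp(A.max(axis=0)); rw /= rw.sum()
        exp_c = sum(aw[i] * atoms[i] for i in range(3))
        exp_p = sum(rw[j] * res[j] for j in range(4))
        np.testing.assert_allclose(c_ctx.data[0], exp_c, atol=1e-10)
        np.testing.assert_allclose(p_ctx.data[0], exp_p, atol=1e-10)


class TestAffinityHead:
    def test_zero_weights_output_is_bias(self, micro_model, rng):
        zero_parameters(micro_model)
        micro_model.aff_out.bias.data[:] = 3.25
        out = micro_model.predict_affinity(Tensor(rng.standard_normal((1, 4))),
                                           Tensor(rng.standard_normal((1, 4))),
                                           Tensor(rng.standard_normal((1, 4))))
        assert out.item() == pytest.approx(3.25)

    def test_hand_computed_single_hidden_layer(self):
        m = CPIModel(ModelConfig(d0=6, d1=1, n_conv_layers=1, gnn_layers=1,
                                 kernel_size=3))
        m.aff_hidden.weight.data = np.array([[1.0], [2.0], [3.0]])
        m.aff_hidden.bias.data[:] = 0.5
        m.aff_out.weight.data = np.array([[2.0]])
        m.aff_out.bias.data[:] = -1.0
        out = m.predict_affinity(Tensor([[1.0]]), Tensor([[1.0]]),
                                 Tensor([[1.0]]))
        # hidden = leaky(1 + 2 + 3 + 0.5) = 6.5; out = 2 * 6.5 - 1 = 12
        assert out.item() == pytest.approx(12.0)

    def test_linear_scaling_with_identity_hidden(self):
        m = CPIModel(ModelConfig(d0=6, d1=1, n_conv_layers=1, gnn_layers=1,
                                 kernel_size=3))
        m.aff_hidden.weight.data = np.array([[1.0], [0.0], [0.0]])
        m.aff_hidden.bias.data[:] = 0
        m.aff_out.weight.data = np.array([[1.0]])
        m.aff_out.bias.data[:] = 0
        one = m.predict_affinity(Tensor([[2.0]]), Tensor([[0.0]]),
                                 Tensor([[0.0]])).item()
        ten = m.predict_affinity(Tensor([[20.0]]), Tensor([[0.0]]),
                                 Tensor([[0.0]])).item()
        assert ten == pytest.approx(10 * one)


class TestForward:
    def test_default_routing_instrumentation(self, small_dataset):
        records, proteins, _ = small_dataset
        model = CPIModel(ModelConfig(d0=32, d1=8, seed=1))
        cap = {}
        _forward(model, records[0], proteins, cap)
        assert cap["site_routing"] == "combine"
        assert cap["affinity_routing"] == "evo"
        np.testing.assert_array_equal(cap["site_rep"], cap["p_combine"])
        np.testing.assert_array_equal(cap["affinity_rep"], cap["p_evo"])

    def test_alpha_zero_routing_equivalence(self, small_dataset):
        """At alpha=0, P_combine == P_evo, so routing both heads through
        either representation gives identical predictions."""
        records, proteins, _ = small_dataset
        base = dict(d0=32, d1=8, alpha=0.0, seed=3)
        m_combine = CPIModel(ModelConfig(**base, site_routing="combine",
                                         affinity_routing="combine"))
        m_evo = CPIModel(ModelConfig(**base, site_routing="evo",
                                     affinity_routing="evo"))
        p1 = _forward(m_combine, records[0], proteins)
        p2 = _forward(m_evo, records[0], proteins)
        np.testing.assert_array_equal(p1.site_probs, p2.site_probs)
        assert p1.affinity == p2.affinity

    def test_forward_is_deterministic(self, small_dataset):
        records, proteins, _ = small_dataset
        model = CPIModel(ModelConfig(d0=32, d1=8, seed=2))
        p1 = _forward(model, records[1], proteins)
        p2 = _forward(model, records[1], proteins)
        np.testing.assert_array_equal(p1.site_probs, p2.site_probs)
        assert p1.affinity == p2.affinity

    def test_site_probs_open_interval_many_weight_draws(self, small_dataset):
        records, proteins, _ = small_dataset
        for seed in range(100):
            model = CPIModel(ModelConfig(d0=32, d1=4, n_conv_layers=1,
                                         gnn_layers=1, seed=seed))
            pred = _forward(model, records[0], proteins)
            assert pred.site_probs.min() > 0
            assert pred.site_probs.max() < 1

    def test_atom_permutation_permutes_rows_affinity_invariant(
            self, small_dataset, rng):
        from cpinet.compound import smiles_to_graph
        records, proteins, _ = small_dataset
        model = CPIModel(ModelConfig(d0=32, d1=8, seed=5))
        rec = records[0]
        prot = proteins[rec.protein_id]
        graph = smiles_to_graph(rec.smiles)
        p0u, blu = model.protein.unfold_inputs(prot.embedding, prot.sequence)
        probs, aff = model.forward_tensors(graph, p0u, blu)
        perm = rng.permutation(graph.n_atoms)
        probs_p, aff_p = model.forward_tensors(permute_graph(graph, perm),
                                               p0u, blu)
        np.testing.assert_allclose(probs_p.data,
                                   probs.data[np.argsort(perm)], atol=1e-5)
        assert aff_p.item() == pytest.approx(aff.item(), abs=1e-5)

    def test_bad_smiles_error_carries_pair_id(self, small_dataset):
        from cpinet.io_data import CPIRecord
        _, proteins, _ = small_dataset
        pid = next(iter(proteins))
        model = CPIModel(ModelConfig(d0=32, d1=4, seed=0))
        with pytest.raises(ValueError, match="pairX"):
            model.forward(CPIRecord("pairX", ")(", pid), proteins[pid])


class TestPIM:
    def test_from_sparse(self):
        lab = pim_from_sparse({(0, 1), (2, 3)}, 3, 4)
        assert lab.pim.shape == (3, 4)
        assert lab.pim.sum() == 2
        assert lab.pim[0, 1] == 1 and lab.pim[2, 3] == 1

    def test_bounds_checked(self):
        with pytest.raises(ValueError, match="out of bounds"):
            pim_from_sparse({(3, 0)}, 3, 4)

    def test_binary_invariant(self):
        with pytest.raises(ValueError, match="0 or 1"):
            PairwiseInteractionLabel(np.array([[0.5]]))


def test_checkpoint_round_trip(tmp_path, small_dataset):
    records, proteins, _ = small_dataset
    model = CPIModel(ModelConfig(d0=32, d1=8, seed=9))
    model.save(tmp_path / "ckpt.npz")
    loaded = CPIModel.load(tmp_path / "ckpt.npz")
    assert loaded.config == model.config
    p1 = _forward(model, records[0], proteins)
    p2 = _forward(loaded, records[0], proteins)
    np.testing.assert_array_equal(p1.site_probs, p2.site_probs)
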