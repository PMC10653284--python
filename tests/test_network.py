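import numpy as np
import pytest
from rdkit import Chem

from polyscreen import build_vocabulary, featurize
from polyscreen.model import ModelError, export_bond_states
from polyscreen.nn import (
    BondGraphNetwork,
    Tensor,
    Adam,
    absolute,
    add,
    backward,
    batch_graphs,
    concat,
    masked_mae_loss,
    matmul,
    mul_const,
    relu,
    spmm,
    one_hot_csr,
    sum_all,
)

SMILES = ["OCCOC(=O)CCCCC(=O)O", "NCCCCCC(=O)NCCCCCC(=O)O", "CCO"]


@pytest.fixture(scope="module")
def vocab():
    return build_vocabulary(SMILES)


@pytest.fixture(scope="module")
def net(vocab):
    return BondGraphNetwork(
        n_atom_tokens=vocab.n_atom_tokens,
        n_bond_tokens=vocab.n_bond_tokens,
        atom_dim=12,
        bond_dim=12,
        n_layers=3,
        n_outputs=8,
        rng=np.random.default_rng(0),
    )


class TestAutodiff:
    def test_gradients_match_finite_differences(self, vocab):
        """Autodiff gradients through a full forward+loss agree with
        central differences on sampled weights."""
        net = BondGraphNetwork(
            vocab.n_atom_tokens, vocab.n_bond_tokens, 6, 6, 2, 8,
            np.random.default_rng(1),
        )
        # give the zero-initialized readout nonzero values so the loss is
        # sensitive to every layer
        rng = np.random.default_rng(2)
        net.W_out.data = rng.normal(0, 0.3, net.W_out.data.shape).astype(np.float32)
        batch = batch_graphs([featurize(s, vocab) for s in SMILES])
        target = rng.normal(size=(3, 8))
        mask = np.ones((3, 8), dtype=bool)

        def loss_value():
            pred, _ = net.forward(batch)
            return float(masked_mae_loss(pred, target, mask).data)

        pred, _ = net.forward(batch)
        loss = masked_mae_loss(pred, target, mask)
        for p in net.parameters():
            p.grad = None
        backward(loss)

        eps = 1e-2
        checked = 0
        for p in [net.atom_emb, net.layers[0]["Wa2"], net.layers[1]["Wb1"], net.W_out]:
            flat = p.data.ravel()
            idx = rng.choice(len(flat), size=3, replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                up = loss_value()
                flat[i] = orig - eps
                down = loss_value()
                flat[i] = orig
                numeric = (up - down) / (2 * eps)
                analytic = p.grad.ravel()[i]
                assert analytic == pytest.approx(numeric, abs=5e-3), (numeric, analytic)
                checked += 1
        assert checked == 12

    def test_spmm_matches_dense(self, rng):
        idx = np.array([2, 0, 1, 1])
        S = one_hot_csr(idx, 3)
        a = Tensor(rng.normal(size=(3, 4)))
        out = spmm(S, a)
        assert np.allclose(out.data, a.data[idx])
        backward(sum_all(out))
        expected = np.zeros((3, 4))
        np.add.at(expected, idx, np.ones((4, 4)))
        assert np.allclose(a.grad, expected)


class TestForward:
    def test_bond_sum_identity_untrained(self, net, vocab):
        batch = batch_graphs([featurize(s, vocab) for s in SMILES])
        pred, contrib = net.forward(batch)
        sums = np.zeros_like(pred.data)
        np.add.at(sums, batch.bond_graph, contrib.data)
        denom = np.maximum(np.abs(pred.data), 1e-8)
        assert (np.abs(sums - pred.data) / denom).max() < 1e-4

    def test_permutation_invariance(self, net, vocab, rng):
        smiles = SMILES[0]
        mol = Chem.MolFromSmiles(smiles)
        perm = [int(i) for i in rng.permutation(mol.GetNumAtoms())]
        renumbered = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm))
        p1, _ = net.forward(batch_graphs([featurize(smiles, vocab)]))
        p2, _ = net.forward(batch_graphs([featurize(renumbered, vocab)]))
        assert np.allclose(p1.data, p2.data, atol=1e-4)

    def test_weight_identical_models_agree(self, net, vocab):
        clone = BondGraphNetwork(
            vocab.n_atom_tokens, vocab.n_bond_tokens, 12, 12, 3, 8,
            np.random.default_rng(99),
        )
        clone.set_weights(net.get_weights())
        batch = batch_graphs([featurize(SMILES[1], vocab)])
        p1, _ = net.forward(batch)
        p2, _ = clone.forward(batch)
        assert np.array_equal(p1.data, p2.data)

    def test_empty_graph_rejected(self, vocab):
        with pytest.raises(ValueError, match="empty"):
            batch_graphs([featurize("[Na+]", vocab)])

    def test_batching_matches_single_graphs(self, net, vocab):
        graphs = [featurize(s, vocab) for s in SMILES]
        batched, _ = net.forward(batch_graphs(graphs))
        singles = np.stack(
            [net.forward(batch_graphs([g]))[0].data[0] for g in graphs]
        )
        assert np.allclose(batched.data, singles, atol=1e-4)


class TestMaskedLossGradients:
    def test_masked_slots_do_not_affect_gradients(self, net, vocab, rng):
        batch = batch_graphs([featurize(s, vocab) for s in SMILES])
        target = rng.normal(size=(3, 8))
        mask = rng.random((3, 8)) < 0.5
        mask[0, 0] = True  # keep at least one observed entry

        def grads(t):
            pred, _ = net.forward(batch)
            loss = masked_mae_loss(pred, t, mask)
            for p in net.parameters():
                p.grad = None
            backward(loss)
            return float(loss.data), [
                None if p.grad is None else p.grad.copy() for p in net.parameters()
            ]

        perturbed = target.copy()
        perturbed[~mask] = 1e6
        l1, g1 = grads(target)
        l2, g2 = grads(perturbed)
        assert l1 == l2
        for a, b in zip(g1, g2):
            assert (a is None and b is None) or np.array_equal(a, b)


class TestBondStates:
    def test_layer0_states_determined_by_token(self, net, vocab):
        g = featurize("CCCCC", vocab)
        states = export_bond_states(net, g, 0)
        assert states.shape == (4, 12)
        # all four C-C bonds share one token and therefore one initial state
        assert np.allclose(states, states[0])

    def test_row_count_and_layer_range(self, net, vocab):
        g = featurize(SMILES[0], vocab)
        mol = Chem.MolFromSmiles(SMILES[0])
        for layer in range(net.n_layers + 1):
            assert export_bond_states(net, g, layer).shape[0] == mol.GetNumBonds()
        with pytest.raises(ModelError, match="out of range"):
            export_bond_states(net, g, net.n_layers + 1)


def test_adam_reduces_simple_loss(rng):
    w = Tensor(np.array([[5.0]]))
    opt = Adam([w], lr=0.1)
    for _ in range(200):
        loss = sum_all(absolute(w))
        opt.zero_grad()
        backward(loss)
        opt.step()
    assert abs(w.data.item()) < 0.2
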