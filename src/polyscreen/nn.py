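"""Graph-network engine: reverse-mode autodiff on NumPy arrays, the
bond-centred message-passing network, and the Adam optimizer.

The network alternates bond and atom state updates for a configured number
of message-passing layers.  Each bond update sees the two endpoint atom
states, the current bond state and a per-graph global context through a
two-layer perceptron with a residual connection; atom updates aggregate
incident bond states the same way; the global state accumulates a
sum-pooled summary of the atom states (sum pooling, so chain size is
visible to the readout).  The readout maps every final bond state to one
scalar per property and sums over bonds, which makes the per-bond values an
exact additive decomposition of the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

DTYPE = np.float32

# ---------------------------------------------------------------------------
# autodiff core


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        data = np.asarray(data)
        if data.dtype != DTYPE:
            data = data.astype(DTYPE)
        self.data = data
        self.grad = None
        self.parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def backward(loss: Tensor) -> None:
    order: list[Tensor] = []
    seen: set[int] = set()

    stack = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))

    loss.grad = np.ones_like(loss.data)
    for node in reversed(order):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return Tensor(a.data + b.data, (a, b), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accumulate(a, g @ b.data.T)
        _accumulate(b, a.data.T @ g)

    return Tensor(a.data @ b.data, (a, b), bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bw(g):
        _accumulate(a, g * mask)

    return Tensor(a.data * mask, (a,), bw)


def absolute(a: Tensor) -> Tensor:
    sign = np.sign(a.data)

    def bw(g):
        _accumulate(a, g * sign)

    return Tensor(np.abs(a.data), (a,), bw)


def mul_const(a: Tensor, c) -> Tensor:
    def bw(g):
        _accumulate(a, g * c)

    return Tensor(a.data * c, (a,), bw)


def sub_const(a: Tensor, c) -> Tensor:
    def bw(g):
        _accumulate(a, g)

    return Tensor(a.data - c, (a,), bw)


def gather(a: Tensor, idx: np.ndarray) -> Tensor:
    def bw(g):
        z = np.zeros_like(a.data)
        np.add.at(z, idx, g)
        _accumulate(a, z)

    return Tensor(a.data[idx], (a,), bw)


def segment_sum(a: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    out = np.zeros((n_segments,) + a.data.shape[1:], dtype=a.data.dtype)
    np.add.at(out, seg, a.data)

    def bw(g):
        _accumulate(a, g[seg])

    return Tensor(out, (a,), bw)


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the last axis."""
    widths = [t.data.shape[-1] for t in tensors]
    offsets = np.cumsum([0] + widths)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            _accumulate(t, g[..., lo:hi])

    return Tensor(np.concatenate([t.data for t in tensors], axis=-1), tuple(tensors), bw)


def sum_all(a: Tensor) -> Tensor:
    def bw(g):
        _accumulate(a, np.full_like(a.data, float(g)))

    return Tensor(np.asarray(a.data.sum()), (a,), bw)


def spmm(S, a: Tensor) -> Tensor:
    """Multiply a constant sparse matrix with a tensor: out = S @ a.

    One CSR matrix expresses a gather (one-hot rows) or a segment sum
    (one-hot columns); its transpose is the backward map.
    """

    def bw(g):
        _accumulate(a, S.T @ g)

    return Tensor(S @ a.data, (a,), bw)


def one_hot_csr(idx: np.ndarray, n_cols: int) -> sparse.csr_matrix:
    """Gather matrix: row i selects column idx[i]."""
    n = len(idx)
    return sparse.csr_matrix(
        (np.ones(n, dtype=DTYPE), (np.arange(n), idx)), shape=(n, n_cols)
    )


def scatter_csr(rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int]) -> sparse.csr_matrix:
    """Aggregation matrix summing entry (rows[k], cols[k]) occurrences."""
    return sparse.csr_matrix(
        (np.ones(len(rows), dtype=DTYPE), (rows, cols)), shape=shape
    )


# ---------------------------------------------------------------------------
# graph batching


@dataclass
class GraphBatch:
    """Disjoint union of molecular graphs with segment bookkeeping."""

    atom_ids: np.ndarray
    bond_ids: np.ndarray
    bond_u: np.ndarray  # one endpoint per undirected bond
    bond_v: np.ndarray
    edge_dst: np.ndarray  # target atom per directed edge
    edge_bond: np.ndarray  # undirected bond per directed edge
    atom_graph: np.ndarray  # graph id per atom
    bond_graph: np.ndarray  # graph id per bond
    n_graphs: int
    _mats: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    @property
    def n_bonds(self) -> int:
        return len(self.bond_ids)

    def mats(self, n_atom_tokens: int, n_bond_tokens: int) -> dict:
        """Sparse gather/aggregate matrices for message passing, built once
        per batch."""
        key = (n_atom_tokens, n_bond_tokens)
        if key not in self._mats:
            self._mats[key] = {
                # embedding lookups
                "EA": one_hot_csr(self.atom_ids, n_atom_tokens),
                "EB": one_hot_csr(self.bond_ids, n_bond_tokens),
                "EG": one_hot_csr(np.zeros(self.n_graphs, dtype=np.int64), 1),
                # bond endpoints
                "U": one_hot_csr(self.bond_u, self.n_atoms),
                "V": one_hot_csr(self.bond_v, self.n_atoms),
                # bond->atom message aggregation over directed edges
                "C": scatter_csr(
                    self.edge_dst, self.edge_bond, (self.n_atoms, self.n_bonds)
                ),
                # graph pooling / broadcast
                "P": scatter_csr(
                    self.atom_graph,
                    np.arange(self.n_atoms),
                    (self.n_graphs, self.n_atoms),
                ),
                "Q": scatter_csr(
                    self.bond_graph,
                    np.arange(self.n_bonds),
                    (self.n_graphs, self.n_bonds),
                ),
            }
            m = self._mats[key]
            m = self._mats[key]
            m["Pt"] = m["P"].T.tocsr()
            m["Qt"] = m["Q"].T.tocsr()
            # row-normalized pooling and a log-size feature: the global
            # state sees bounded averages plus explicit chain size
            counts = np.asarray(m["P"].sum(axis=1)).ravel()
            m["Pm"] = (sparse.diags((1.0 / counts).astype(DTYPE)) @ m["P"]).tocsr()
            m["log_size"] = np.log(counts).astype(DTYPE)[:, None]
        return self._mats[key]


def batch_graphs(graphs) -> GraphBatch:
    """Concatenate :class:`~polyscreen.featurize.MoleculeGraph` objects into
    one disjoint-union batch.  Raises on a graph with no atoms or bonds."""
    atom_ids, bond_ids = [], []
    bond_u, bond_v = [], []
    edge_dst, edge_bond = [], []
    atom_graph, bond_graph = [], []
    atom_off = bond_off = 0
    for gi, g in enumerate(graphs):
        if g.n_atoms == 0 or g.n_bonds == 0:
            raise ValueError("cannot batch an empty or bond-free graph")
        atom_ids.append(g.atom_indices)
        bond_ids.append(g.bond_indices)
        und = g.edges[::2]  # first direction of each bond
        bond_u.append(und[:, 0] + atom_off)
        bond_v.append(und[:, 1] + atom_off)
        edge_dst.append(g.edges[:, 1] + atom_off)
        edge_bond.append(g.edge_bond + bond_off)
        atom_graph.append(np.full(g.n_atoms, gi, dtype=np.int64))
        bond_graph.append(np.full(g.n_bonds, gi, dtype=np.int64))
        atom_off += g.n_atoms
        bond_off += g.n_bonds
    return GraphBatch(
        atom_ids=np.concatenate(atom_ids),
        bond_ids=np.concatenate(bond_ids),
        bond_u=np.concatenate(bond_u),
        bond_v=np.concatenate(bond_v),
        edge_dst=np.concatenate(edge_dst),
        edge_bond=np.concatenate(edge_bond),
        atom_graph=np.concatenate(atom_graph),
        bond_graph=np.concatenate(bond_graph),
        n_graphs=len(list(graphs)),
    )


# ---------------------------------------------------------------------------
# network


class BondGraphNetwork:
    """Multi-output message-passing network with a bond-sum readout."""

    def __init__(
        self,
        n_atom_tokens: int,
        n_bond_tokens: int,
        atom_dim: int,
        bond_dim: int,
        n_layers: int,
        n_outputs: int,
        rng: np.random.Generator,
    ):
        self.n_layers = n_layers
        self.atom_dim = atom_dim
        self.bond_dim = bond_dim
        self.n_outputs = n_outputs
        gdim = atom_dim
        self.global_dim = gdim

        def glorot(shape, scale=1.0):
            std = scale * np.sqrt(2.0 / sum(shape))
            return Tensor(rng.normal(0.0, std, size=shape))

        def zeros(shape):
            return Tensor(np.zeros(shape))

        # residual branches are down-scaled with depth so activations stay
        # bounded in deep stacks
        res = 1.0 / np.sqrt(max(n_layers, 1))

        self.atom_emb = glorot((n_atom_tokens, atom_dim))
        self.bond_emb = glorot((n_bond_tokens, bond_dim))
        self.global_init = zeros((1, gdim))

        in_dim = atom_dim + bond_dim + gdim
        self.layers = []
        for li in range(n_layers):
            layer = {
                "Wb1": glorot((in_dim, bond_dim)),
                "bb1": zeros((bond_dim,)),
                "Wb2": glorot((bond_dim, bond_dim), scale=res),
                "bb2": zeros((bond_dim,)),
            }
            if li < n_layers - 1:
                # the readout consumes only bond states, so atom/global
                # updates after the final bond update would be dead weight
                layer.update(
                    {
                        "Wa1": glorot((in_dim, atom_dim)),
                        "ba1": zeros((atom_dim,)),
                        "Wa2": glorot((atom_dim, atom_dim), scale=res),
                        "ba2": zeros((atom_dim,)),
                        "Wg1": glorot((gdim + atom_dim + 1, gdim)),
                        "bg1": zeros((gdim,)),
                        "Wg2": glorot((gdim, gdim), scale=res),
                        "bg2": zeros((gdim,)),
                    }
                )
            self.layers.append(layer)
        # zero-initialized readout: an untrained net predicts 0 for every
        # property instead of an O(n_bonds) random sum
        self.W_out = zeros((bond_dim, n_outputs))
        self.b_out = zeros((n_outputs,))

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[Tensor]:
        params = [self.atom_emb, self.bond_emb, self.global_init]
        for layer in self.layers:
            params.extend(layer.values())
        params.extend([self.W_out, self.b_out])
        return params

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p.data = w.copy()

    # -- forward ------------------------------------------------------------

    def _mlp(self, x: Tensor, layer, prefix: str) -> Tensor:
        h = relu(add(matmul(x, layer[f"W{prefix}1"]), layer[f"b{prefix}1"]))
        return add(matmul(h, layer[f"W{prefix}2"]), layer[f"b{prefix}2"])

    def forward(
        self, batch: GraphBatch, collect_bond_states: bool = False
    ):
        """Run message passing.

        Returns (per-graph predictions (n_graphs, n_outputs), per-bond
        contributions (n_bonds, n_outputs), [bond states per layer]).
        Predictions are exactly the per-graph sums of the contributions.
        """
        m = batch.mats(self.atom_emb.shape[0], self.bond_emb.shape[0])
        A = spmm(m["EA"], self.atom_emb)
        B = spmm(m["EB"], self.bond_emb)
        G = spmm(m["EG"], self.global_init)

        states = [B.data.copy()] if collect_bond_states else None

        for layer in self.layers:
            pair = add(spmm(m["U"], A), spmm(m["V"], A))
            bond_in = concat([pair, B, spmm(m["Qt"], G)])
            B = add(B, self._mlp(bond_in, layer, "b"))

            if "Wa1" in layer:
                messages = spmm(m["C"], B)
                atom_in = concat([A, messages, spmm(m["Pt"], G)])
                A = add(A, self._mlp(atom_in, layer, "a"))

                pooled = spmm(m["Pm"], A)  # mean pooling, bounded in size
                g_in = concat([G, pooled, Tensor(m["log_size"])])
                G = add(G, self._mlp(g_in, layer, "g"))

            if collect_bond_states:
                states.append(B.data.copy())

        contrib = add(matmul(B, self.W_out), self.b_out)
        pred = spmm(m["Q"], contrib)
        if collect_bond_states:
            return pred, contrib, states
        return pred, contrib


def masked_mae_loss(pred: Tensor, target: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean absolute error over unmasked entries of the batch; 0 when the
    batch is fully masked."""
    n = float(mask.sum())
    if n == 0:
        return mul_const(sum_all(mul_const(pred, np.zeros_like(mask, dtype=float))), 0.0)
    diff = sub_const(pred, np.where(mask, target, pred.data))
    return mul_const(sum_all(absolute(mul_const(diff, mask.astype(float)))), 1.0 / n)


class Adam:
    """Adam optimizer with global-norm gradient clipping; per-epoch
    exponential learning-rate decay is applied externally via ``set_lr``."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        beta1=0.9,
        beta2=0.999,
        eps=1e-8,
        clip_norm: float | None = 5.0,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def set_lr(self, lr: float) -> None:
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        if self.clip_norm is not None:
            norm = np.sqrt(
                sum(
                    float((p.grad**2).sum())
                    for p in self.params
                    if p.grad is not None
                )
            )
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
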