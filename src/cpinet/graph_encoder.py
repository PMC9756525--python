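"""Compound graph encoder: message passing + super-node exchange.

Atom states are updated by summing messages from bonded neighbours
(a linear map of the neighbour state concatenated with the bond features),
then exchanged with a molecule-level *super node* through gated "warp"
updates.  The super node gives every atom a two-hop view of the whole
molecule and doubles as the global compound feature used by the affinity
head.

Warp update (both directions gated by a sigmoid of the two endpoints):

    g_s    = sigmoid(U_s [meanpool(atoms); s])
    s'     = g_s * tanh(W_a meanpool(atoms)) + (1 - g_s) * s
    g_i    = sigmoid(U_a [atom_i; s])
    atom'  = g_i * tanh(W_s s) + (1 - g_i) * atom_i

With all weights zero the gates sit at 1/2 and each update halves the
state — a fixed point structure the tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concat, gather_rows, segment_sum
from .compound import CompoundGraph, F_ATOM, F_BOND
from .nn import Linear

__all__ = ["GraphState", "GraphEncoder"]


@dataclass
class GraphState:
    """Per-atom states (N_m x d1), the super-node state (1 x d1), and the
    number of message-passing layers applied so far."""

    atom_states: Tensor
    super_state: Tensor
    layer_index: int = 0


class _WarpUnit:
    def __init__(self, d1: int, rng: np.random.Generator):
        self.super_cand = Linear(d1, d1, rng)   # W_a
        self.super_gate = Linear(2 * d1, d1, rng)
        self.atom_cand = Linear(d1, d1, rng)    # W_s
        self.atom_gate = Linear(2 * d1, d1, rng)

    def parameters(self):
        return (self.super_cand.parameters() + self.super_gate.parameters()
                + self.atom_cand.parameters() + self.atom_gate.parameters())


class _MessageUnit:
    def __init__(self, d1: int, rng: np.random.Generator):
        self.msg = Linear(d1 + F_BOND, d1, rng)   # W_msg
        self.self_update = Linear(d1, d1, rng)    # W_self

    def parameters(self):
        return self.msg.parameters() + self.self_update.parameters()


class GraphEncoder:
    """Stacked message-passing / warp-exchange layers over a compound graph."""

    def __init__(self, d1: int, n_layers: int = 3, leaky_slope: float = 0.01,
                 rng: np.random.Generator | None = None, f_atom: int = F_ATOM):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.d1 = d1
        self.n_layers = n_layers
        self.leaky_slope = leaky_slope
        self.proj = Linear(f_atom, d1, rng)
        self.message_units = [_MessageUnit(d1, rng) for _ in range(n_layers)]
        self.warp_units = [_WarpUnit(d1, rng) for _ in range(n_layers)]

    # -- operations --------------------------------------------------------

    def init_state(self, graph: CompoundGraph) -> GraphState:
        """Project raw atom features to width d1; the super node starts as
        the mean of the projected atom states."""
        atoms = self.proj(as_tensor(graph.atom_features))
        return GraphState(atoms, atoms.mean(axis=0, keepdims=True), 0)

    def message_pass(self, state: GraphState, graph: CompoundGraph,
                     layer: int) -> GraphState:
        """Sum neighbour messages along bonds and update each atom.

        atom_i' = LeakyReLU(W_self atom_i + sum_j W_msg [atom_j; bond_ij]);
        isolated atoms receive a zero message.
        """
        unit = self.message_units[layer]
        atoms = state.atom_states
        n = atoms.shape[0]
        if len(graph.edge_src):
            src_states = gather_rows(atoms, graph.edge_src)
            edge_in = concat([src_states, as_tensor(graph.bond_features)],
                             axis=1)
            messages = segment_sum(unit.msg(edge_in), graph.edge_dst, n)
        else:
            messages = as_tensor(np.zeros((n, self.d1)))
        new_atoms = (unit.self_update(atoms) + messages).leaky_relu(
            self.leaky_slope)
        return GraphState(new_atoms, state.super_state, state.layer_index)

    def warp_exchange(self, state: GraphState, layer: int) -> GraphState:
        """Gated exchange between the atom states and the super node."""
        unit = self.warp_units[layer]
        atoms, s = state.atom_states, state.super_state
        n = atoms.shape[0]
        pooled = atoms.mean(axis=0, keepdims=True)            # (1, d1)
        g_s = concat([pooled, s], axis=1)
        g_s = unit.super_gate(g_s).sigmoid()
        new_s = g_s * unit.super_cand(pooled).tanh() + (1.0 - g_s) * s
        s_rows = gather_rows(s, np.zeros(n, dtype=np.intp))   # broadcast s
        g_a = unit.atom_gate(concat([atoms, s_rows], axis=1)).sigmoid()
        cand = gather_rows(unit.atom_cand(s).tanh(), np.zeros(n, dtype=np.intp))
        new_atoms = g_a * cand + (1.0 - g_a) * atoms
        return GraphState(new_atoms, new_s, state.layer_index + 1)

    def encode(self, graph: CompoundGraph) -> tuple[Tensor, Tensor]:
        """Full pass: returns (final atom states N_m x d1, super state 1 x d1)."""
        state = self.init_state(graph)
        for layer in range(self.n_layers):
            state = self.message_pass(state, graph, layer)
            state = self.warp_exchange(state, layer)
        return state.atom_states, state.super_state

    def parameters(self) -> list[Tensor]:
        out = self.proj.parameters()
        for unit in self.message_units:
            out.extend(unit.parameters())
        for unit in self.warp_units:
            out.extend(unit.parameters())
        return out
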