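"""Joint interaction-site + binding-affinity model.

The forward pass encodes the compound graph (per-atom vectors plus a
super-node summary) and the protein (P_embed / P_evo / P_combine, all
N_p x d1), then applies two heads:

* **site head** — per-side fully connected maps followed by a dot product
  and sigmoid give the probability that atom i contacts residue j:
  ``y_ij = sigmoid(fc_c(atom_i) . fc_p(residue_j))``.  The protein side
  consumes P_combine by default.
* **affinity head** — a dual attention over the bilinear compatibility
  ``A = tanh(atoms W_att residues^T)`` yields a compound context (softmax
  over row maxima) and a protein context (softmax over column maxima);
  these plus the super node feed a small fully connected stack producing
  the scalar affinity (-log10 Ki/Kd scale, no output nonlinearity).  The
  protein side consumes P_evo by default.

The per-head routing (combine / evo / embed) is configurable; the defaults
are the operating point selected in the original study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, as_tensor, concat, softmax
from .compound import CompoundGraph, F_ATOM, smiles_to_graph
from .graph_encoder import GraphEncoder
from .io_data import CPIRecord, ProteinEntry
from .nn import Linear
from .protein import ProteinFeaturizer, blosum_encode, combine

__all__ = ["ModelConfig", "InteractionPrediction", "PairwiseInteractionLabel",
           "CPIModel", "pim_from_sparse"]

_ROUTES = ("combine", "evo", "embed")


@dataclass
class ModelConfig:
    """Hyperparameters of the joint model (defaults follow the reference
    operating point: d1=128, N=4 protein conv layers, alpha=0.5,
    sites read P_combine, affinity reads P_evo)."""

    d0: int = 768
    d1: int = 128
    n_conv_layers: int = 4
    gnn_layers: int = 3
    alpha: float = 0.5
    kernel_size: int = 7
    leaky_slope: float = 0.01
    site_routing: str = "combine"
    affinity_routing: str = "evo"
    standardize_blosum: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        for route in (self.site_routing, self.affinity_routing):
            if route not in _ROUTES:
                raise ValueError(f"routing must be one of {_ROUTES}, "
                                 f"got '{route}'")


@dataclass
class InteractionPrediction:
    """Predicted probability matrix (N_m x N_p, entries in (0,1)) plus the
    scalar affinity prediction for one pair."""

    site_probs: np.ndarray
    affinity: float


@dataclass
class PairwiseInteractionLabel:
    """Dense binary contact matrix built from sparse (atom, residue) pairs."""

    pim: np.ndarray

    def __post_init__(self) -> None:
        vals = np.unique(self.pim)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("PIM entries must be 0 or 1")


def pim_from_sparse(site_labels: set[tuple[int, int]], n_atoms: int,
                    n_residues: int) -> PairwiseInteractionLabel:
    pim = np.zeros((n_atoms, n_residues))
    for a, r in site_labels:
        if not (0 <= a < n_atoms and 0 <= r < n_residues):
            raise ValueError(f"site label ({a}, {r}) out of bounds for "
                             f"{n_atoms} x {n_residues}")
        pim[a, r] = 1.0
    return PairwiseInteractionLabel(pim)


class CPIModel:
    """The joint site + affinity predictor."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.protein = ProteinFeaturizer(
            d0=cfg.d0, d1=cfg.d1, n_layers=cfg.n_conv_layers,
            kernel_size=cfg.kernel_size, leaky_slope=cfg.leaky_slope,
            standardize_blosum=cfg.standardize_blosum, rng=rng)
        self.encoder = GraphEncoder(cfg.d1, n_layers=cfg.gnn_layers,
                                    leaky_slope=cfg.leaky_slope, rng=rng)
        self.site_fc_atom = Linear(cfg.d1, cfg.d1, rng)
        self.site_fc_res = Linear(cfg.d1, cfg.d1, rng)
        self.att_weight = Tensor(
            rng.uniform(-1, 1, size=(cfg.d1, cfg.d1)) / np.sqrt(cfg.d1),
            requires_grad=True)
        self.aff_hidden = Linear(3 * cfg.d1, cfg.d1, rng)
        self.aff_out = Linear(cfg.d1, 1, rng)

    # -- heads -------------------------------------------------------------

    def predict_sites(self, atom_feats: Tensor, residue_feats: Tensor) -> Tensor:
        """sigmoid(fc_c(atoms) @ fc_p(residues)^T) — an (N_m, N_p) tensor."""
        if atom_feats.shape[1] != residue_feats.shape[1]:
            raise ValueError("atom and residue feature widths differ")
        return (self.site_fc_atom(atom_feats)
                @ self.site_fc_res(residue_feats).T).sigmoid()

    def dual_attention(self, atom_feats: Tensor,
                       residue_feats: Tensor) -> tuple[Tensor, Tensor]:
        """Max-pooled bilinear attention giving one context per side."""
        compat = (atom_feats @ self.att_weight @ residue_feats.T).tanh()
        atom_w = softmax(compat.max(axis=1, keepdims=True), axis=0)  # (N_m,1)
        res_w = softmax(compat.max(axis=0, keepdims=True), axis=1)   # (1,N_p)
        compound_ctx = atom_w.T @ atom_feats                          # (1,d1)
        protein_ctx = res_w @ residue_feats                           # (1,d1)
        return compound_ctx, protein_ctx

    def predict_affinity(self, compound_ctx: Tensor, protein_ctx: Tensor,
                         super_final: Tensor) -> Tensor:
        """Scalar regression head on the concatenated contexts."""
        h = concat([compound_ctx, protein_ctx, super_final], axis=1)
        h = self.aff_hidden(h).leaky_relu(self.config.leaky_slope)
        return self.aff_out(h).reshape(())

    # -- full forward ------------------------------------------------------

    def forward_tensors(self, graph: CompoundGraph,
                        p0_unfolded: np.ndarray,
                        blosum_unfolded: np.ndarray,
                        capture: dict | None = None) -> tuple[Tensor, Tensor]:
        """Differentiable forward pass from precomputed protein unfolds.

        Returns (site_probs tensor, affinity tensor).  If `capture` is a
        dict it receives the intermediate representations, including which
        representation each head consumed (instrumentation hook).
        """
        cfg = self.config
        atom_feats, super_final = self.encoder.encode(graph)
        p_embed = self.protein.p_embed_from_unfolded(p0_unfolded)
        p_evo = self.protein.p_evo_from_unfolded(blosum_unfolded)
        reps = {"embed": p_embed, "evo": p_evo,
                "combine": combine(p_embed, p_evo, cfg.alpha)}
        site_rep = reps[cfg.site_routing]
        aff_rep = reps[cfg.affinity_routing]
        site_probs = self.predict_sites(atom_feats, site_rep)
        compound_ctx, protein_ctx = self.dual_attention(atom_feats, aff_rep)
        affinity = self.predict_affinity(compound_ctx, protein_ctx,
                                         super_final)
        if capture is not None:
            capture.update(
                site_routing=cfg.site_routing,
                affinity_routing=cfg.affinity_routing,
                site_rep=site_rep.data, affinity_rep=aff_rep.data,
                p_embed=p_embed.data, p_evo=p_evo.data,
                p_combine=reps["combine"].data,
                atom_feats=atom_feats.data, super_final=super_final.data)
        return site_probs, affinity

    def forward(self, record: CPIRecord, protein: ProteinEntry,
                capture: dict | None = None) -> InteractionPrediction:
        """Featurize one pair and predict; errors carry the pair id."""
        try:
            graph = smiles_to_graph(record.smiles)
        except ValueError as exc:
            raise ValueError(f"pair {record.pair_id}: {exc}") from exc
        p0u, blu = self.protein.unfold_inputs(protein.embedding,
                                              protein.sequence)
        site_probs, affinity = self.forward_tensors(graph, p0u, blu, capture)
        probs = np.clip(site_probs.data, 1e-12, 1.0 - 1e-12)
        return InteractionPrediction(site_probs=probs,
                                     affinity=float(affinity.data))

    # -- persistence -------------------------------------------------------

    def parameters(self) -> list[Tensor]:
        return (self.protein.parameters() + self.encoder.parameters()
                + self.site_fc_atom.parameters()
                + self.site_fc_res.parameters() + [self.att_weight]
                + self.aff_hidden.parameters() + self.aff_out.parameters())

    def save(self, path: str | Path) -> None:
        """One-file checkpoint: weights (npz) with the config embedded."""
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        arrays["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CPIModel":
        with np.load(path) as data:
            cfg = ModelConfig(**json.loads(
                bytes(data["config_json"]).decode()))
            model = cls(cfg)
            for i, p in enumerate(model.parameters()):
                loaded = data[f"param_{i}"]
                if loaded.shape != p.data.shape:
                    raise ValueError(f"checkpoint parameter {i} has shape "
                                     f"{loaded.shape}, expected "
                                     f"{p.data.shape}")
                p.data = loaded.astype(np.float64)
        return model
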