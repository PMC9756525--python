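"""Protein representations: embedding CNN, BLOSUM62 evolutionary CNN, blend.

Three per-residue representations of width ``d1`` are produced:

* ``P_embed`` — the precomputed self-supervised embedding matrix
  (N_p x d0) passed through N same-length 1-D convolution + LeakyReLU
  layers, the first reducing d0 -> d1, the rest d1 -> d1;
* ``P_evo``  — the sequence encoded row-wise by the BLOSUM62 substitution
  matrix (N_p x 20) and passed through a CNN of the same shape;
* ``P_combine = alpha * P_embed + (1 - alpha) * P_evo`` — a convex blend;
  alpha = 0.5 is the default operating point.

Convolutions run along the residue axis with an odd kernel (default 7) and
symmetric zero padding, so N_p is preserved everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .autodiff import Tensor, as_tensor, unfold1d
from .nn import Conv1dSame

__all__ = [
    "AMINO_ACIDS",
    "blosum62_matrix",
    "blosum_encode",
    "combine",
    "ProteinFeaturizer",
    "ProteinRepresentation",
]

#: Canonical residue order for the 20-column BLOSUM62 encoding.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_BLOSUM62: np.ndarray | None = None
_BLOSUM62_STD: np.ndarray | None = None


def blosum62_matrix(standardize: bool = False) -> np.ndarray:
    """The 20x20 BLOSUM62 substitution matrix, rows/cols in
    :data:`AMINO_ACIDS` order.  With ``standardize=True`` each column is
    z-scored (zero mean, unit variance) across the 20 residues."""
    global _BLOSUM62, _BLOSUM62_STD
    if _BLOSUM62 is None:
        table = substitution_matrices.load("BLOSUM62")
        m = np.empty((20, 20))
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                m[i, j] = table[a, b]
        _BLOSUM62 = m
        _BLOSUM62_STD = (m - m.mean(axis=0)) / m.std(axis=0)
    return _BLOSUM62_STD if standardize else _BLOSUM62


def blosum_encode(sequence: str, standardize: bool = False) -> np.ndarray:
    """Encode a sequence as its per-residue BLOSUM62 score rows.

    Returns an (N_p, 20) matrix; 'X' residues become zero rows.  Raises
    ``ValueError`` for an empty sequence or a letter outside the 20
    standard residues + 'X' (naming the offending position).
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    table = blosum62_matrix(standardize)
    out = np.zeros((len(sequence), 20))
    for i, aa in enumerate(sequence):
        if aa == "X":
            continue
        idx = AMINO_ACIDS.find(aa)
        if idx < 0:
            raise ValueError(f"unknown residue '{aa}' at position {i}")
        out[i] = table[idx]
    return out


def combine(p_embed, p_evo, alpha: float):
    """Convex blend alpha * P_embed + (1 - alpha) * P_evo.

    Works on plain arrays and on autodiff tensors; shapes must match and
    alpha must lie in [0, 1].
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    a_shape = p_embed.shape
    if a_shape != p_evo.shape:
        raise ValueError(f"shape mismatch: {a_shape} vs {p_evo.shape}")
    return p_embed * alpha + p_evo * (1.0 - alpha)


@dataclass
class ProteinRepresentation:
    """The three N_p x d1 representations for one protein."""

    p_embed: np.ndarray
    p_evo: np.ndarray
    p_combine: np.ndarray
    alpha: float
    d1: int
    n_layers: int

    def __post_init__(self) -> None:
        if not (self.p_embed.shape == self.p_evo.shape
                == self.p_combine.shape):
            raise ValueError("representation matrices must share one shape")
        expected = combine(self.p_embed, self.p_evo, self.alpha)
        if np.max(np.abs(self.p_combine - expected)) > 1e-6:
            raise ValueError("p_combine is not the alpha blend of "
                             "p_embed and p_evo")


def conv_stack(x: Tensor, layers: list[Conv1dSame], slope: float) -> Tensor:
    """Apply conv -> LeakyReLU for each layer in order (empty list = identity)."""
    for layer in layers:
        x = layer(x).leaky_relu(slope)
    return x


class ProteinFeaturizer:
    """Owns the two protein CNNs and produces all three representations.

    Parameters
    ----------
    d0 : embedding input width (768 or 1900 typically).
    d1 : representation width, default 128.
    n_layers : total conv layers N per CNN, default 4 (one reducing layer
        followed by N - 1 width-preserving layers).
    kernel_size : odd convolution width along the residue axis, default 7.
    """

    def __init__(self, d0: int, d1: int = 128, n_layers: int = 4,
                 kernel_size: int = 7, leaky_slope: float = 0.01,
                 standardize_blosum: bool = False,
                 rng: np.random.Generator | None = None):
        if n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.d0, self.d1, self.n_layers = d0, d1, n_layers
        self.kernel_size = kernel_size
        self.leaky_slope = leaky_slope
        self.standardize_blosum = standardize_blosum
        self.embed_layers = [Conv1dSame(d0, d1, kernel_size, rng)] + [
            Conv1dSame(d1, d1, kernel_size, rng) for _ in range(n_layers - 1)]
        self.evo_layers = [Conv1dSame(20, d1, kernel_size, rng)] + [
            Conv1dSame(d1, d1, kernel_size, rng) for _ in range(n_layers - 1)]

    # -- spec-level operations --------------------------------------------

    def embed_reduce(self, p0) -> Tensor:
        """First conv layer: (N_p, d0) -> (N_p, d1) via LeakyReLU(conv)."""
        p0 = as_tensor(p0)
        if p0.shape[0] < 1:
            raise ValueError("protein must have at least one residue")
        return self.embed_layers[0](p0).leaky_relu(self.leaky_slope)

    def embed_stack(self, p1) -> Tensor:
        """Remaining N - 1 conv layers, width preserved (P_embed)."""
        return conv_stack(as_tensor(p1), self.embed_layers[1:],
                          self.leaky_slope)

    def evo_encode(self, blosum_mat) -> Tensor:
        """Full evolutionary CNN: (N_p, 20) BLOSUM encoding -> (N_p, d1)."""
        x = as_tensor(blosum_mat)
        if x.shape[0] < 1:
            raise ValueError("protein must have at least one residue")
        return conv_stack(x, self.evo_layers, self.leaky_slope)

    # -- full pipelines ----------------------------------------------------

    def p_embed_from_unfolded(self, p0_unfolded: Tensor | np.ndarray) -> Tensor:
        """P_embed from a precomputed unfold of P_0 (the unfold does not
        depend on the weights, so it can be cached per protein)."""
        x = self.embed_layers[0].from_unfolded(as_tensor(p0_unfolded))
        x = x.leaky_relu(self.leaky_slope)
        return conv_stack(x, self.embed_layers[1:], self.leaky_slope)

    def p_evo_from_unfolded(self, blosum_unfolded: Tensor | np.ndarray) -> Tensor:
        x = self.evo_layers[0].from_unfolded(as_tensor(blosum_unfolded))
        x = x.leaky_relu(self.leaky_slope)
        return conv_stack(x, self.evo_layers[1:], self.leaky_slope)

    def unfold_inputs(self, embedding: np.ndarray,
                      sequence: str) -> tuple[np.ndarray, np.ndarray]:
        """Cacheable im2col of the two raw inputs."""
        p0u = unfold1d(Tensor(embedding), self.kernel_size).data
        bl = blosum_encode(sequence, self.standardize_blosum)
        blu = unfold1d(Tensor(bl), self.kernel_size).data
        return p0u, blu

    def represent(self, embedding: np.ndarray, sequence: str,
                  alpha: float) -> ProteinRepresentation:
        """Evaluate both CNNs and the blend, returning plain arrays."""
        p0u, blu = self.unfold_inputs(embedding, sequence)
        p_embed = self.p_embed_from_unfolded(p0u).data
        p_evo = self.p_evo_from_unfolded(blu).data
        return ProteinRepresentation(
            p_embed=p_embed, p_evo=p_evo,
            p_combine=combine(p_embed, p_evo, alpha),
            alpha=alpha, d1=self.d1, n_layers=self.n_layers)

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for layer in self.embed_layers + self.evo_layers:
            out.extend(layer.parameters())
        return out
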