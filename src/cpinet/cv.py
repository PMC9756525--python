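"""Clustering-based cross-validation (cold splits).

Compounds and proteins are clustered by single linkage at a distance
threshold (0.3–0.6 is the useful range); folds are then built so that test
items come from clusters absent in training:

* ``new_compound`` — compound clusters are partitioned across folds
  (default 5); a test pair's compound cluster never appears in training.
* ``new_protein`` — the same for protein clusters (default 5).
* ``both_new``    — compound clusters and protein clusters are each
  partitioned into g groups (default 3, giving g² = 9 folds); the test
  fold is one (compound-group, protein-group) cell and training uses only
  cells sharing neither the row nor the column, so both the compound and
  the protein of every test pair are unseen.

Distances: compounds use 1 − Tanimoto similarity of Morgan fingerprints
(radius 2, 2048 bits); proteins use 1 − identity fraction from a global
alignment (BLOSUM62, gap open −11 / extend −1).  Cluster edges use strict
inequality (dist < threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io_data import CPIRecord

__all__ = ["FoldAssignment", "compound_distance_matrix",
           "protein_distance_matrix", "single_linkage_clusters",
           "make_folds", "audit_fold_assignment", "write_folds",
           "read_folds"]

SETTINGS = ("new_compound", "new_protein", "both_new")
DEFAULT_FOLDS = {"new_compound": 5, "new_protein": 5, "both_new": 9}


@dataclass
class FoldAssignment:
    """Cluster labels plus per-fold train/test membership."""

    setting: str
    threshold: float
    n_folds: int
    pair_ids: list[str]
    fold_of_pair: dict[str, int]
    compound_cluster: dict[str, int]       # smiles -> cluster id
    protein_cluster: dict[str, int]        # protein_id -> cluster id
    # per-pair group on each axis (equal to the fold for the single-axis
    # settings; row/column of the grid cell for both_new)
    compound_group_of_pair: dict[str, int] = field(default_factory=dict)
    protein_group_of_pair: dict[str, int] = field(default_factory=dict)

    def train_test(self, fold: int) -> tuple[list[str], list[str]]:
        """Pair ids for training and testing in the given fold.

        For both_new, pairs sharing the test cell's compound-group row or
        protein-group column are excluded from training entirely.
        """
        if not 0 <= fold < self.n_folds:
            raise ValueError(f"fold must be in [0, {self.n_folds})")
        test = [p for p in self.pair_ids if self.fold_of_pair[p] == fold]
        if self.setting == "both_new":
            g = int(round(np.sqrt(self.n_folds)))
            row, col = divmod(fold, g)
            train = [p for p in self.pair_ids
                     if self.compound_group_of_pair[p] != row
                     and self.protein_group_of_pair[p] != col]
        else:
            train = [p for p in self.pair_ids if self.fold_of_pair[p] != fold]
        return train, test


def compound_distance_matrix(smiles_list: list[str]) -> np.ndarray:
    """1 − Tanimoto similarity of Morgan fingerprints (radius 2, 2048 bits)."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    fps = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: '{smi}'")
        fps.append(gen.GetFingerprint(mol))
    n = len(fps)
    dist = np.zeros((n, n))
    for i in range(n):
        if i + 1 < n:
            sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1:])
            dist[i, i + 1:] = 1.0 - np.asarray(sims)
            dist[i + 1:, i] = dist[i, i + 1:]
    return dist


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def protein_distance_matrix(sequences: list[str]) -> np.ndarray:
    """1 − (identities / alignment length) from global alignment."""
    for s in sequences:
        if not s:
            raise ValueError("empty protein sequence")
    aligner = _aligner()
    n = len(sequences)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(sequences[i], sequences[j])[0]
            counts = aln.counts()
            length = counts.gaps + counts.identities + counts.mismatches
            d = 1.0 - counts.identities / length if length else 1.0
            dist[i, j] = dist[j, i] = d
    return dist


def single_linkage_clusters(dist: np.ndarray, threshold: float) -> np.ndarray:
    """Single-linkage clusters at cut height `threshold`.

    At a fixed cut, single linkage equals the connected components of the
    graph with an edge wherever dist < threshold (strict).  Labels are
    dense integers ordered by each cluster's smallest member index.
    """
    dist = np.asarray(dist, dtype=np.float64)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(dist) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    adj = csr_matrix(dist < threshold)
    _, raw = connected_components(adj, directed=False)
    # relabel so cluster k is the k-th distinct label by first appearance
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap)
        labels[i] = remap[lab]
    return labels


def _balanced_groups(cluster_ids: list[int], weights: dict[int, int],
                     n_groups: int,
                     rng: np.random.Generator) -> dict[int, int]:
    """Greedy size-balanced assignment of clusters to groups.

    Clusters are visited in decreasing pair-count order (seeded shuffle
    breaks ties), each going to the currently lightest group.
    """
    order = list(cluster_ids)
    rng.shuffle(order)
    order.sort(key=lambda c: -weights[c])
    loads = np.zeros(n_groups)
    assignment: dict[int, int] = {}
    for c in order:
        g = int(np.argmin(loads))
        assignment[c] = g
        loads[g] += weights[c]
    return assignment


def make_folds(records: list[CPIRecord], sequences: dict[str, str],
               setting: str, threshold: float = 0.3,
               n_folds: int | None = None, seed: int = 0) -> FoldAssignment:
    """Build a leakage-free fold assignment for one CV setting.

    `sequences` maps protein_id -> amino-acid sequence for every protein
    referenced by `records`.  The assignment is audited before return.
    """
    if setting not in SETTINGS:
        raise ValueError(f"setting must be one of {SETTINGS}")
    n_folds = DEFAULT_FOLDS[setting] if n_folds is None else n_folds
    rng = np.random.default_rng(seed)

    smiles = sorted({r.smiles for r in records})
    prot_ids = sorted({r.protein_id for r in records})
    comp_labels = single_linkage_clusters(
        compound_distance_matrix(smiles), threshold)
    prot_labels = single_linkage_clusters(
        protein_distance_matrix([sequences[p] for p in prot_ids]), threshold)
    compound_cluster = dict(zip(smiles, (int(v) for v in comp_labels)))
    protein_cluster = dict(zip(prot_ids, (int(v) for v in prot_labels)))

    comp_weight: dict[int, int] = {}
    prot_weight: dict[int, int] = {}
    for r in records:
        cc = compound_cluster[r.smiles]
        pc = protein_cluster[r.protein_id]
        comp_weight[cc] = comp_weight.get(cc, 0) + 1
        prot_weight[pc] = prot_weight.get(pc, 0) + 1

    fa = FoldAssignment(setting=setting, threshold=threshold,
                        n_folds=n_folds,
                        pair_ids=[r.pair_id for r in records],
                        fold_of_pair={},
                        compound_cluster=compound_cluster,
                        protein_cluster=protein_cluster)

    if setting in ("new_compound", "new_protein"):
        weights = comp_weight if setting == "new_compound" else prot_weight
        if len(weights) < n_folds:
            raise ValueError(
                f"{setting}: only {len(weights)} clusters for {n_folds} "
                f"folds at threshold {threshold}")
        groups = _balanced_groups(sorted(weights), weights, n_folds, rng)
        for r in records:
            cid = (compound_cluster[r.smiles] if setting == "new_compound"
                   else protein_cluster[r.protein_id])
            fold = groups[cid]
            fa.fold_of_pair[r.pair_id] = fold
            fa.compound_group_of_pair[r.pair_id] = fold
            fa.protein_group_of_pair[r.pair_id] = fold
    else:
        g = int(round(np.sqrt(n_folds)))
        if g * g != n_folds:
            raise ValueError(f"both_new needs a square fold count, "
                             f"got {n_folds}")
        if len(comp_weight) < g or len(prot_weight) < g:
            raise ValueError(
                f"both_new: need at least {g} compound and protein "
                f"clusters, have {len(comp_weight)} and "
                f"{len(prot_weight)} at threshold {threshold}")
        cgroups = _balanced_groups(sorted(comp_weight), comp_weight, g, rng)
        pgroups = _balanced_groups(sorted(prot_weight), prot_weight, g, rng)
        for r in records:
            row = cgroups[compound_cluster[r.smiles]]
            col = pgroups[protein_cluster[r.protein_id]]
            fa.compound_group_of_pair[r.pair_id] = row
            fa.protein_group_of_pair[r.pair_id] = col
            fa.fold_of_pair[r.pair_id] = g * row + col

    audit_fold_assignment(fa, records)
    return fa


def audit_fold_assignment(fa: FoldAssignment,
                          records: list[CPIRecord]) -> int:
    """Exhaustive leakage audit; raises on any train/test cluster overlap.

    Returns the number of (fold, pair, pair) comparisons performed.
    """
    by_id = {r.pair_id: r for r in records}
    checked = 0
    for fold in range(fa.n_folds):
        train, test = fa.train_test(fold)
        train_cc = {fa.compound_cluster[by_id[p].smiles] for p in train}
        train_pc = {fa.protein_cluster[by_id[p].protein_id] for p in train}
        for p in test:
            checked += len(train)
            cc = fa.compound_cluster[by_id[p].smiles]
            pc = fa.protein_cluster[by_id[p].protein_id]
            if fa.setting in ("new_compound", "both_new") and cc in train_cc:
                raise AssertionError(
                    f"fold {fold}: test pair {p} shares compound cluster "
                    f"{cc} with training")
            if fa.setting in ("new_protein", "both_new") and pc in train_pc:
                raise AssertionError(
                    f"fold {fold}: test pair {p} shares protein cluster "
                    f"{pc} with training")
    return checked


def write_folds(fa: FoldAssignment, path: str | Path) -> None:
    """TSV with columns pair_id, fold, role (train|test)."""
    with open(path, "w") as fh:
        fh.write("pair_id\tfold\trole\n")
        for fold in range(fa.n_folds):
            train, test = fa.train_test(fold)
            for p in train:
                fh.write(f"{p}\t{fold}\ttrain\n")
            for p in test:
                fh.write(f"{p}\t{fold}\ttest\n")


def read_folds(path: str | Path) -> dict[int, dict[str, list[str]]]:
    """Inverse of :func:`write_folds`: fold -> {'train': [...], 'test': [...]}."""
    out: dict[int, dict[str, list[str]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("pair_id"):
            raise ValueError(f"{path}: missing folds header")
        for line in fh:
            if not line.strip():
                continue
            pair_id, fold, role = line.rstrip("\n").split("\t")
            out.setdefault(int(fold), {"train": [], "test": []})[
                role].append(pair_id)
    return out
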