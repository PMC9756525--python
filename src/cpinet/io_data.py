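"""On-disk data contract: pairs table, protein store, site labels, predictions.

All indices in files are 0-based.  Formats:

* ``pairs.tsv`` — TSV with header ``pair_id  smiles  protein_id  affinity``;
  an empty affinity cell means the pair has no binding-affinity label
  (affinities are on the -log10 Ki/Kd scale throughout).
* ``proteins.fasta`` — one record per protein, id matching the pairs table.
* ``embeddings.h5`` — HDF5, one float dataset per protein id of shape
  (sequence length, d0); d0 is typically 768 (structure/BERT-style
  per-residue embeddings) or 1900 (UniRep-style).
* ``sites.tsv`` — TSV ``pair_id  atom_index  residue_index``, one
  non-covalent contact per row; atoms index the heavy atoms of the SMILES
  in parser order, residues index the protein sequence.
* predictions — ``affinity_pred.tsv`` (pair_id, affinity) and
  ``sites_pred.tsv`` (pair_id, atom_index, residue_index, probability).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from Bio import SeqIO

__all__ = [
    "CPIRecord",
    "ProteinEntry",
    "read_pairs_table",
    "write_pairs_table",
    "read_protein_store",
    "write_protein_store",
    "read_site_labels",
    "write_site_labels",
    "write_predictions",
    "read_predictions",
    "validate_dataset",
]

PAIRS_COLUMNS = ("pair_id", "smiles", "protein_id", "affinity")
EXPECTED_EMBED_DIMS = (768, 1900)


@dataclass
class CPIRecord:
    """One compound-protein pair."""

    pair_id: str
    smiles: str
    protein_id: str
    affinity: float | None = None
    site_labels: set[tuple[int, int]] = field(default_factory=set)


@dataclass
class ProteinEntry:
    """A protein sequence plus its per-residue embedding matrix."""

    protein_id: str
    sequence: str
    embedding: np.ndarray  # (len(sequence), d0)

    def __post_init__(self) -> None:
        self.embedding = np.asarray(self.embedding, dtype=np.float64)
        if self.embedding.ndim != 2:
            raise ValueError(
                f"protein {self.protein_id}: embedding must be 2-D, "
                f"got shape {self.embedding.shape}")
        if self.embedding.shape[0] != len(self.sequence):
            raise ValueError(
                f"protein {self.protein_id}: length mismatch — sequence has "
                f"{len(self.sequence)} residues but embedding has "
                f"{self.embedding.shape[0]} rows")
        if self.embedding.shape[1] not in EXPECTED_EMBED_DIMS:
            warnings.warn(
                f"protein {self.protein_id}: embedding width "
                f"{self.embedding.shape[1]} is not one of the usual "
                f"{EXPECTED_EMBED_DIMS}", stacklevel=2)


def read_pairs_table(path: str | Path) -> list[CPIRecord]:
    """Read a pairs TSV, preserving row order.

    Raises ``ValueError`` on a missing/malformed header, a malformed row
    (with its line number) or a duplicated pair_id (named in the message).
    """
    path = Path(path)
    records: list[CPIRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected header "
                             f"{PAIRS_COLUMNS}") from None
        if tuple(header) != PAIRS_COLUMNS:
            raise ValueError(f"{path}: bad header {header!r}, expected "
                             f"{list(PAIRS_COLUMNS)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, "
                                 f"got {len(row)}")
            pair_id, smiles, protein_id, aff_cell = row
            if pair_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate pair_id "
                                 f"'{pair_id}'")
            seen.add(pair_id)
            if aff_cell.strip() == "":
                affinity = None
            else:
                try:
                    affinity = float(aff_cell)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: affinity '{aff_cell}' is not a "
                        f"number") from None
                if not math.isfinite(affinity):
                    raise ValueError(f"{path}:{lineno}: affinity must be "
                                     f"finite")
            records.append(CPIRecord(pair_id, smiles, protein_id, affinity))
    return records


def write_pairs_table(records: list[CPIRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(PAIRS_COLUMNS) + "\n")
        for r in records:
            aff = "" if r.affinity is None else format(r.affinity, ".6f")
            fh.write(f"{r.pair_id}\t{r.smiles}\t{r.protein_id}\t{aff}\n")


def read_protein_store(fasta_path: str | Path,
                       embed_path: str | Path) -> dict[str, ProteinEntry]:
    """Load sequences and embeddings; every FASTA id must have an embedding
    whose row count equals the sequence length."""
    entries: dict[str, ProteinEntry] = {}
    with h5py.File(embed_path, "r") as h5:
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            pid = rec.id
            if pid in entries:
                raise ValueError(f"{fasta_path}: duplicate protein id "
                                 f"'{pid}'")
            if pid not in h5:
                raise ValueError(f"protein '{pid}' present in {fasta_path} "
                                 f"but missing from {embed_path}")
            entries[pid] = ProteinEntry(pid, str(rec.seq), h5[pid][()])
    return entries


def write_protein_store(entries: dict[str, ProteinEntry],
                        fasta_path: str | Path,
                        embed_path: str | Path) -> None:
    """Inverse of :func:`read_protein_store`; byte-stable for fixed input."""
    with open(fasta_path, "w") as fh:
        for pid in entries:
            fh.write(f">{pid}\n{entries[pid].sequence}\n")
    with h5py.File(embed_path, "w") as h5:
        for pid, entry in entries.items():
            # track_times=False keeps the file byte-identical across reruns
            h5.create_dataset(pid, data=entry.embedding, track_times=False)


def read_site_labels(path: str | Path) -> dict[str, set[tuple[int, int]]]:
    """Read sparse contact triplets; duplicates collapse, absent pairs are
    simply missing from the map (treat as empty set)."""
    path = Path(path)
    labels: dict[str, set[tuple[int, int]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is not None and header[:1] and header[0] != "pair_id":
            raise ValueError(f"{path}: expected header starting with "
                             f"'pair_id', got {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            pair_id, a_cell, r_cell = row
            try:
                atom_idx, res_idx = int(a_cell), int(r_cell)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: indices must be "
                                 f"integers") from None
            if atom_idx < 0 or res_idx < 0:
                raise ValueError(f"{path}:{lineno}: negative index "
                                 f"({atom_idx}, {res_idx})")
            labels.setdefault(pair_id, set()).add((atom_idx, res_idx))
    return labels


def write_site_labels(labels: dict[str, set[tuple[int, int]]],
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id\tatom_index\tresidue_index\n")
        for pair_id in labels:
            for atom_idx, res_idx in sorted(labels[pair_id]):
                fh.write(f"{pair_id}\t{atom_idx}\t{res_idx}\n")


def write_predictions(records, predictions, out_dir: str | Path,
                      threshold: float = 0.0) -> tuple[Path, Path]:
    """Write affinity and sparse site predictions.

    `predictions` holds one object per record with ``site_probs``
    (N_m x N_p array) and ``affinity`` (scalar).  Site entries with
    probability >= `threshold` are written (default 0.0 = all).
    """
    if len(records) != len(predictions):
        raise ValueError(f"{len(records)} records but {len(predictions)} "
                         f"predictions")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff_path = out_dir / "affinity_pred.tsv"
    sites_path = out_dir / "sites_pred.tsv"
    with open(aff_path, "w") as fh:
        fh.write("pair_id\taffinity\n")
        for rec, pred in zip(records, predictions):
            fh.write(f"{rec.pair_id}\t{float(pred.affinity):.6f}\n")
    with open(sites_path, "w") as fh:
        fh.write("pair_id\tatom_index\tresidue_index\tprobability\n")
        for rec, pred in zip(records, predictions):
            probs = np.asarray(pred.site_probs)
            if probs.ndim != 2:
                raise ValueError(f"pair {rec.pair_id}: site_probs must be "
                                 f"2-D, got shape {probs.shape}")
            if rec.site_labels:
                max_a = max(a for a, _ in rec.site_labels)
                max_r = max(r for _, r in rec.site_labels)
                if max_a >= probs.shape[0] or max_r >= probs.shape[1]:
                    raise ValueError(
                        f"pair {rec.pair_id}: prediction shape "
                        f"{probs.shape} cannot hold site label "
                        f"({max_a}, {max_r})")
            rows, cols = np.nonzero(probs >= threshold)
            for i, j in zip(rows, cols):
                fh.write(f"{rec.pair_id}\t{i}\t{j}\t{probs[i, j]:.6f}\n")
    return aff_path, sites_path


def read_predictions(out_dir: str | Path):
    """Read back what :func:`write_predictions` wrote.

    Returns (affinity map pair_id -> float,
             sparse site map pair_id -> {(atom, residue): probability}).
    """
    out_dir = Path(out_dir)
    affinities: dict[str, float] = {}
    with open(out_dir / "affinity_pred.tsv", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            if row:
                affinities[row[0]] = float(row[1])
    sites: dict[str, dict[tuple[int, int], float]] = {}
    with open(out_dir / "sites_pred.tsv", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            if row:
                pid, a, r, p = row
                sites.setdefault(pid, {})[(int(a), int(r))] = float(p)
    return affinities, sites


def validate_dataset(records: list[CPIRecord],
                     proteins: dict[str, ProteinEntry]) -> None:
    """Full validation sweep: every protein resolvable, every site label in
    bounds once the pair is featurized.  Raises ``ValueError`` on the first
    violation."""
    from .compound import smiles_to_graph

    n_atoms_cache: dict[str, int] = {}
    for rec in records:
        if rec.protein_id not in proteins:
            raise ValueError(f"pair {rec.pair_id}: unknown protein "
                             f"'{rec.protein_id}'")
        if rec.smiles not in n_atoms_cache:
            n_atoms_cache[rec.smiles] = smiles_to_graph(rec.smiles).n_atoms
        n_m = n_atoms_cache[rec.smiles]
        n_p = len(proteins[rec.protein_id].sequence)
        for atom_idx, res_idx in rec.site_labels:
            if not (0 <= atom_idx < n_m and 0 <= res_idx < n_p):
                raise ValueError(
                    f"pair {rec.pair_id}: site label ({atom_idx}, "
                    f"{res_idx}) out of bounds for {n_m} atoms x {n_p} "
                    f"residues")
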