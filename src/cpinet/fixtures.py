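"""Seeded synthetic datasets with a planted, learnable interaction rule.

Stands in for a curated structure-derived corpus so the whole pipeline is
testable offline.  What is emulated:

* **Proteins** — random sequences (uniform over the 20 residues) of
  length 30–80.  Each residue carries a hidden class in {0, 1, 2}; the
  embedding row is the class's direction vector (three orthonormal
  directions in R^d0, scaled to norm 6) plus isotropic Gaussian noise
  (sd 0.5).  The class signal lives only in the embedding, not in the
  sequence, so models reading the embedding pathway can learn the site
  rule while sequence-only models cannot.
* **Contacts** — atom i contacts residue j with probability ``p_hi``
  (default 0.8) when the residue's hidden class is 0 and the atom is a
  heteroatom (N/O/S), else ``p_lo`` (default 0.02).
* **Affinity** — ``a * log(1 + n_contacts) + b`` plus Gaussian noise
  (a=2, b=4, sd 0.3 by default), dropped with probability 0.4 to emulate
  pairs that have contact labels but no measured Ki/Kd.
* **Compounds** — drawn from a bundled vocabulary of ~30 drug-like
  SMILES (guaranteed parseable).

An identical :class:`FixtureSpec` regenerates byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .compound import smiles_to_graph
from .io_data import (CPIRecord, ProteinEntry, write_pairs_table,
                      write_protein_store, write_site_labels)

__all__ = ["SMILES_VOCAB", "FixtureSpec", "SyntheticProtein", "gen_protein",
           "gen_pair", "gen_dataset_in_memory", "gen_dataset",
           "planted_probability_matrix"]

#: Bundled drug-like molecules (common small-molecule drugs).
SMILES_VOCAB = (
    "CC(=O)Oc1ccccc1C(=O)O",                          # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",                     # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",                     # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",                             # paracetamol
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",                   # naproxen
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",                  # salbutamol
    "CN1CCCC1c1cccnc1",                               # nicotine
    "NCCc1c[nH]cn1",                                  # histamine
    "NCCc1c[nH]c2ccc(O)cc12",                         # serotonin
    "NCCc1ccc(O)c(O)c1",                              # dopamine
    "CNCC(O)c1ccc(O)c(O)c1",                          # adrenaline
    "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",          # warfarin
    "CN1c2ccc(Cl)cc2C(=NCC1=O)c1ccccc1",              # diazepam
    "O=C1NC(=O)C(N1)(c1ccccc1)c1ccccc1",              # phenytoin
    "Nc1ccc(cc1)S(N)(=O)=O",                          # sulfanilamide
    "COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC",                # trimethoprim
    "Cc1ncc([N+](=O)[O-])n1CCO",                      # metronidazole
    "CCN(CC)CCOC(=O)c1ccc(N)cc1",                     # procaine
    "CCN(CC)CC(=O)Nc1c(C)cccc1C",                     # lidocaine
    "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21",               # chlorpromazine
    "CC(C)NCC(O)COc1cccc2ccccc12",                    # propranolol
    "COCCc1ccc(OCC(O)CNC(C)C)cc1",                    # metoprolol
    "Cn1c(=O)c2[nH]cnc2n(C)c1=O",                     # theophylline
    "NNC(=O)c1ccncc1",                                # isoniazid
    "NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl",        # furosemide
    "COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1", # indomethacin
    "Cc1cccc(Nc2ccccc2C(=O)O)c1C",                    # mefenamic acid
    "OCC(NC(=O)C(Cl)Cl)C(O)c1ccc(cc1)[N+](=O)[O-]",   # chloramphenicol
    "Cc1ccc(cc1)-c1cc(nn1-c1ccc(cc1)S(N)(=O)=O)C(F)(F)F",  # celecoxib
    "CNCCC(Oc1ccc(cc1)C(F)(F)F)c1ccccc1",             # fluoxetine
    "NCC1(CC(=O)O)CCCCC1",                            # gabapentin
    "COc1ccc2[nH]cc(CCNC(C)=O)c2c1",                  # melatonin
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
N_CLASSES = 3
CLASS_DIRECTION_NORM = 6.0
EMBED_NOISE_SD = 0.5
_DIRECTION_SEED = 20220913  # fixed: directions are part of the rule

_directions_cache: dict[int, np.ndarray] = {}


def class_directions(d0: int) -> np.ndarray:
    """Three fixed orthonormal directions in R^d0, scaled to norm 6."""
    if d0 not in _directions_cache:
        rng = np.random.default_rng(_DIRECTION_SEED)
        q, _ = np.linalg.qr(rng.standard_normal((d0, N_CLASSES)))
        _directions_cache[d0] = q.T * CLASS_DIRECTION_NORM
    return _directions_cache[d0]


@dataclass
class FixtureSpec:
    """Everything needed to regenerate a dataset byte-identically."""

    n_pairs: int = 20
    protein_length_range: tuple[int, int] = (30, 80)
    d0: int = 768
    n_proteins: int | None = None          # default: ceil(n_pairs / 2)
    p_hi: float = 0.8
    p_lo: float = 0.02
    affinity_scale: float = 2.0            # a in a*log(1+|sites|)+b
    affinity_offset: float = 4.0           # b
    affinity_noise_sd: float = 0.3
    missing_affinity_fraction: float = 0.4
    smiles_vocab: tuple[str, ...] = SMILES_VOCAB
    seed: int = 0

    def resolved_n_proteins(self) -> int:
        if self.n_proteins is not None:
            return self.n_proteins
        return max(3, math.ceil(self.n_pairs / 2))


@dataclass
class SyntheticProtein:
    """A generated protein plus its hidden per-residue classes."""

    entry: ProteinEntry
    classes: np.ndarray   # (N_p,) ints in {0, 1, 2}


def gen_protein(length: int, d0: int,
                rng: np.random.Generator | int,
                protein_id: str = "prot") -> SyntheticProtein:
    """Generate one protein with class-structured embeddings."""
    if length < 1:
        raise ValueError("protein length must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    seq = "".join(AMINO_ACIDS[i]
                  for i in rng.integers(0, 20, size=length))
    classes = rng.integers(0, N_CLASSES, size=length)
    emb = (class_directions(d0)[classes]
           + rng.normal(0.0, EMBED_NOISE_SD, size=(length, d0)))
    return SyntheticProtein(ProteinEntry(protein_id, seq, emb), classes)


def planted_probability_matrix(classes: np.ndarray,
                               heteroatom_mask: np.ndarray,
                               p_hi: float = 0.8,
                               p_lo: float = 0.02) -> np.ndarray:
    """The true contact probabilities (N_m x N_p) under the planted rule —
    the Bayes-optimal site scorer for generated data."""
    hi = np.outer(heteroatom_mask.astype(float), (classes == 0).astype(float))
    return p_lo + (p_hi - p_lo) * hi


def gen_pair(protein: SyntheticProtein, smiles: str, spec: FixtureSpec,
             rng: np.random.Generator, pair_id: str) -> CPIRecord:
    """Sample planted contacts and a noisy affinity label for one pair."""
    graph = smiles_to_graph(smiles)
    probs = planted_probability_matrix(protein.classes,
                                       graph.heteroatom_mask,
                                       spec.p_hi, spec.p_lo)
    pim = rng.random(probs.shape) < probs
    sites = {(int(i), int(j)) for i, j in zip(*np.nonzero(pim))}
    affinity = (spec.affinity_scale * math.log1p(len(sites))
                + spec.affinity_offset
                + rng.normal(0.0, spec.affinity_noise_sd))
    if rng.random() < spec.missing_affinity_fraction:
        affinity = None
    return CPIRecord(pair_id=pair_id, smiles=smiles,
                     protein_id=protein.entry.protein_id,
                     affinity=affinity, site_labels=sites)


def gen_dataset_in_memory(spec: FixtureSpec) -> tuple[
        list[CPIRecord], dict[str, ProteinEntry], dict[str, np.ndarray]]:
    """Generate a dataset without touching disk.

    Returns (records, protein store, hidden classes per protein id).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.protein_length_range
    n_prot = spec.resolved_n_proteins()
    prots: dict[str, SyntheticProtein] = {}
    for k in range(n_prot):
        pid = f"prot{k:03d}"
        prots[pid] = gen_protein(int(rng.integers(lo, hi + 1)), spec.d0,
                                 rng, pid)
    pids = list(prots)
    records = []
    for k in range(spec.n_pairs):
        pid = pids[int(rng.integers(len(pids)))]
        smiles = spec.smiles_vocab[int(rng.integers(len(spec.smiles_vocab)))]
        records.append(gen_pair(prots[pid], smiles, spec, rng,
                                pair_id=f"pair{k:04d}"))
    proteins = {pid: sp.entry for pid, sp in prots.items()}
    classes = {pid: sp.classes for pid, sp in prots.items()}
    return records, proteins, classes


def gen_dataset(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write a full dataset (pairs.tsv, proteins.fasta,
    embeddings.h5, sites.tsv, manifest.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, proteins, _ = gen_dataset_in_memory(spec)
    paths = {
        "pairs": out / "pairs.tsv",
        "fasta": out / "proteins.fasta",
        "embeddings": out / "embeddings.h5",
        "sites": out / "sites.tsv",
        "manifest": out / "manifest.json",
    }
    write_pairs_table(records, paths["pairs"])
    write_protein_store(proteins, paths["fasta"], paths["embeddings"])
    write_site_labels({r.pair_id: r.site_labels for r in records
                       if r.site_labels}, paths["sites"])
    manifest = asdict(spec)
    manifest["smiles_vocab"] = list(manifest["smiles_vocab"])
    manifest["protein_length_range"] = list(manifest["protein_length_range"])
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
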