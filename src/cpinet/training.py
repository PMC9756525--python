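"""Multi-objective training: summed site BCE + masked affinity MSE.

The total loss per batch is ``L_total = lambda * L_p + L_a`` with

* ``L_p``  — for each pair, the binary cross-entropy summed over all
  (atom, residue) cells of its contact matrix, averaged over the pairs in
  the batch (probabilities clipped to [eps, 1-eps], eps = 1e-7);
* ``L_a``  — squared error of the predicted affinity, averaged over the
  *labelled* pairs in the batch; unlabelled pairs are masked out of both
  numerator and denominator, so site supervision is still used for every
  pair while only a subset carries an affinity label;
* ``lambda`` — site-loss weight, default 0.1.

Optimisation uses Adam with an initial learning rate of 5e-4 decayed on a
20-epoch step schedule (factor 0.9 per step by default, so the rate stays
within a usable range over a few hundred epochs).  Pairs have different
matrix sizes, so batches are processed pair-by-pair with gradient
accumulation — no padding.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, as_tensor
from .io_data import CPIRecord, ProteinEntry
from .model import CPIModel, ModelConfig, pim_from_sparse
from .nn import Adam

__all__ = ["TrainConfig", "LossReport", "loss_site", "loss_affinity",
           "loss_total", "lr_at_epoch", "train"]

BCE_EPS = 1e-7


@dataclass
class LossReport:
    """Per-step loss decomposition; l_total == lambda * l_p + l_a."""

    l_p: float
    l_a: float
    l_total: float
    lam: float

    def __post_init__(self) -> None:
        if self.l_p < 0 or self.l_a < 0:
            raise ValueError("loss components must be nonnegative")
        if abs(self.l_total - (self.lam * self.l_p + self.l_a)) > 1e-6:
            raise ValueError("l_total does not equal lambda*l_p + l_a")


@dataclass
class TrainConfig:
    """Optimisation settings (defaults: lr 5e-4 with a 20-epoch step
    schedule, lambda 0.1, batches of 16 with per-pair gradient
    accumulation)."""

    learning_rate: float = 5e-4
    lr_step: int = 20
    lr_gamma: float = 0.9
    epochs: int = 200
    batch_size: int = 16
    seed: int = 0
    lam: float = 0.1

    def __post_init__(self) -> None:
        for name in ("learning_rate", "lr_step", "lr_gamma", "epochs",
                     "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


def loss_site(site_probs, pim) -> Tensor:
    """Summed binary cross-entropy over one pair's contact matrix."""
    probs = as_tensor(site_probs)
    pim = np.asarray(pim, dtype=np.float64)
    if probs.shape != pim.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs "
                         f"labels {pim.shape}")
    p = probs.clip(BCE_EPS, 1.0 - BCE_EPS)
    ll = Tensor(pim) * p.log() + Tensor(1.0 - pim) * (1.0 - p).log()
    return -ll.sum()


def loss_affinity(pred, label: float | None) -> Tensor | None:
    """Squared error for one pair, or None when the label is missing."""
    if label is None:
        return None
    diff = as_tensor(pred) - float(label)
    return diff * diff


def loss_total(l_p: float, l_a: float, lam: float = 0.1) -> float:
    """Combine the two objectives: lambda * L_p + L_a."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    return lam * l_p + l_a


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Step schedule: lr * gamma^floor(epoch / step)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.learning_rate * config.lr_gamma ** (epoch // config.lr_step)


@dataclass
class _PairData:
    record: CPIRecord
    graph: object
    p0_unfolded: np.ndarray
    blosum_unfolded: np.ndarray
    pim: np.ndarray


def _prepare(records: list[CPIRecord], proteins: dict[str, ProteinEntry],
             model: CPIModel) -> list[_PairData]:
    from .compound import smiles_to_graph

    graphs: dict[str, object] = {}
    unfolds: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    out = []
    for rec in records:
        if rec.smiles not in graphs:
            graphs[rec.smiles] = smiles_to_graph(rec.smiles)
        graph = graphs[rec.smiles]
        prot = proteins[rec.protein_id]
        if rec.protein_id not in unfolds:
            unfolds[rec.protein_id] = model.protein.unfold_inputs(
                prot.embedding, prot.sequence)
        p0u, blu = unfolds[rec.protein_id]
        pim = pim_from_sparse(rec.site_labels, graph.n_atoms,
                              len(prot.sequence)).pim
        out.append(_PairData(rec, graph, p0u, blu, pim))
    return out


def train(records: list[CPIRecord], proteins: dict[str, ProteinEntry],
          config: TrainConfig | None = None,
          model_config: ModelConfig | None = None,
          model: CPIModel | None = None,
          out_dir: str | Path | None = None,
          log_every: int = 0) -> tuple[CPIModel, list[dict]]:
    """Train the joint model; returns (model, per-epoch history).

    History entries record epoch, lr, l_p, l_a, l_total.  If `out_dir` is
    given, a JSON-lines training log and checkpoints are written there
    (``last.npz`` every epoch, ``best.npz`` tracking the lowest l_total).
    """
    if not records:
        raise ValueError("training set is empty")
    config = config or TrainConfig()
    if model is None:
        mc = model_config or ModelConfig()
        model = CPIModel(mc)
    pairs = _prepare(records, proteins, model)
    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    out_path = Path(out_dir) if out_dir is not None else None
    log_fh = None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        log_fh = open(out_path / "training_log.jsonl", "w")
    best = math.inf
    try:
        for epoch in range(config.epochs):
            opt.lr = lr_at_epoch(config, epoch)
            order = rng.permutation(len(pairs))
            ep_lp, ep_la, ep_nlab = 0.0, 0.0, 0
            for start in range(0, len(order), config.batch_size):
                batch = [pairs[i] for i in order[start:start + config.batch_size]]
                opt.zero_grad()
                site_losses: list[Tensor] = []
                aff_losses: list[Tensor] = []
                for pd in batch:
                    site_probs, affinity = model.forward_tensors(
                        pd.graph, pd.p0_unfolded, pd.blosum_unfolded)
                    site_losses.append(loss_site(site_probs, pd.pim))
                    la = loss_affinity(affinity, pd.record.affinity)
                    if la is not None:
                        aff_losses.append(la)
                l_p = sum(site_losses[1:], site_losses[0]) * (1.0 / len(batch))
                if aff_losses:
                    l_a = sum(aff_losses[1:], aff_losses[0]) * (
                        1.0 / len(aff_losses))
                else:
                    l_a = Tensor(0.0)
                batch_loss = l_p * config.lam + l_a
                lp_val, la_val = float(l_p.data), float(l_a.data)
                lt_val = float(batch_loss.data)
                if not math.isfinite(lt_val):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, pairs "
                        f"{[pd.record.pair_id for pd in batch]}: "
                        f"l_p={lp_val}, l_a={la_val}")
                LossReport(lp_val, la_val, lt_val, config.lam)  # identity check
                batch_loss.backward()
                opt.step()
                ep_lp += lp_val * len(batch)
                ep_la += la_val * len(aff_losses)
                ep_nlab += len(aff_losses)
            n = len(pairs)
            epoch_lp = ep_lp / n
            epoch_la = ep_la / ep_nlab if ep_nlab else 0.0
            entry = {"epoch": epoch, "lr": opt.lr, "l_p": epoch_lp,
                     "l_a": epoch_la,
                     "l_total": loss_total(epoch_lp, epoch_la, config.lam)}
            history.append(entry)
            if log_fh is not None:
                log_fh.write(json.dumps(entry) + "\n")
                log_fh.flush()
            if log_every and (epoch + 1) % log_every == 0:
                print(f"epoch {epoch + 1}/{config.epochs}  "
                      f"l_p={epoch_lp:.4f}  l_a={epoch_la:.4f}")
            if out_path is not None:
                model.save(out_path / "last.npz")
                if entry["l_total"] < best:
                    best = entry["l_total"]
                    model.save(out_path / "best.npz")
    finally:
        if log_fh is not None:
            log_fh.close()
    return model, history
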