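"""Evaluation: ROC-AUC for site prediction, Pearson/RMSE for affinity,
and residue ranking / top-k hit counting for case-study style reports.

Site AUC is computed per pair on the flattened contact matrix (undefined
when a pair has no positive or no negative cell) and macro-averaged over
the pairs where it is defined; a micro (pooled) mode is available.  AUC
uses the Mann-Whitney formulation, so ties contribute 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = ["EvalReport", "auc", "site_auc_per_pair", "pearson", "rmse",
           "rank_residues", "top_k_hits", "evaluate"]


@dataclass
class EvalReport:
    """Aggregate metrics over a set of scored pairs."""

    per_pair_auc: dict[str, float | None]
    mean_auc: float | None
    pearson: float | None
    rmse: float | None
    n_pairs_scored: int

    def __post_init__(self) -> None:
        if self.mean_auc is not None and not 0.0 <= self.mean_auc <= 1.0:
            raise ValueError("mean_auc outside [0, 1]")
        if self.rmse is not None and self.rmse < 0:
            raise ValueError("rmse must be >= 0")
        if self.pearson is not None and not -1.0 <= self.pearson <= 1.0 + 1e-12:
            raise ValueError("pearson outside [-1, 1]")


def auc(scores, labels) -> float | None:
    """Mann-Whitney AUC: (concordant + tied/2) / (n_pos * n_neg).

    Returns None when the labels are degenerate (no positives or no
    negatives).
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)  # average ranks handle ties -> tied/2
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def site_auc_per_pair(site_probs: np.ndarray,
                      pim: np.ndarray) -> float | None:
    """AUC of one pair's flattened contact matrix (None if degenerate)."""
    site_probs = np.asarray(site_probs)
    pim = np.asarray(pim)
    if site_probs.shape != pim.shape:
        raise ValueError(f"shape mismatch: {site_probs.shape} vs {pim.shape}")
    return auc(site_probs.ravel(), pim.ravel())


def pearson(x, y) -> float | None:
    """Pearson correlation; None when either input has zero variance."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size == 0:
        raise ValueError("inputs must have equal nonzero length")
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def rmse(x, y) -> float:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size == 0:
        raise ValueError("inputs must have equal nonzero length")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def rank_residues(site_probs: np.ndarray,
                  reduction: str = "max") -> list[tuple[int, int, float]]:
    """Rank protein residues by contact evidence.

    Residue score = max (default) or mean over atoms of its column.
    Returns (residue_index, rank, score) sorted by descending score; ties
    break toward the lower residue index; ranks are 1-based.
    """
    site_probs = np.asarray(site_probs)
    if site_probs.size == 0:
        raise ValueError("empty probability matrix")
    if reduction == "max":
        scores = site_probs.max(axis=0)
    elif reduction == "mean":
        scores = site_probs.mean(axis=0)
    else:
        raise ValueError(f"unknown reduction '{reduction}'")
    order = np.lexsort((np.arange(scores.size), -scores))
    return [(int(j), rank + 1, float(scores[j]))
            for rank, j in enumerate(order)]


def top_k_hits(ranking: list[tuple[int, int, float]],
               true_residues, k: int) -> int:
    """How many truly contacted residues rank within the top k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    true_set = set(int(r) for r in true_residues)
    return sum(1 for j, rank, _ in ranking if rank <= k and j in true_set)


def evaluate(pair_ids: list[str],
             site_probs: list[np.ndarray] | None,
             pims: list[np.ndarray] | None,
             affinity_pred: list[float] | None = None,
             affinity_true: list[float | None] | None = None,
             site_average: str = "macro") -> EvalReport:
    """Score a set of pairs; degenerate-AUC pairs are excluded from the
    mean, unlabelled affinities from Pearson/RMSE."""
    per_pair: dict[str, float | None] = {}
    mean_auc = None
    if site_probs is not None:
        if site_average == "macro":
            for pid, probs, pim in zip(pair_ids, site_probs, pims):
                per_pair[pid] = site_auc_per_pair(probs, pim)
            defined = [v for v in per_pair.values() if v is not None]
            mean_auc = float(np.mean(defined)) if defined else None
        elif site_average == "micro":
            scores = np.concatenate([np.ravel(p) for p in site_probs])
            labels = np.concatenate([np.ravel(p) for p in pims])
            mean_auc = auc(scores, labels)
            per_pair = {pid: None for pid in pair_ids}
        else:
            raise ValueError(f"unknown site_average '{site_average}'")
    r = p = None
    if affinity_pred is not None and affinity_true is not None:
        pred = [yp for yp, yt in zip(affinity_pred, affinity_true)
                if yt is not None]
        true = [yt for yt in affinity_true if yt is not None]
        if pred:
            p = pearson(pred, true)
            r = rmse(pred, true)
    return EvalReport(per_pair_auc=per_pair, mean_auc=mean_auc,
                      pearson=p, rmse=r, n_pairs_scored=len(pair_ids))
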