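"""Baselines, binarization, and imbalanced-classification metrics.

Sparse networks make link prediction heavily imbalanced toward negatives,
so accuracy is reported as the Matthews correlation coefficient (MCC) and
the G-mean (geometric mean of recall and specificity).  All predictions and
all metrics are restricted to the candidate set of a layer: the node pairs
*not* contained within its observed node set.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np

from .core import MultiplexNetwork, PartialObservation
from .observe import unobserved_pair_mask

__all__ = [
    "ConfusionCounts",
    "random_model",
    "binarize_topk",
    "binarize_threshold",
    "confusion",
    "mcc",
    "gmean",
    "true_missing_counts",
    "evaluate_reconstruction",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def true_missing_counts(truth: MultiplexNetwork, obs: PartialObservation) -> list[int]:
    """Number of true links per layer among that layer's candidate pairs."""
    counts = []
    for lid, a in zip(truth.layer_ids, truth.adjacency):
        cand = unobserved_pair_mask(obs, lid)
        counts.append(int(a[cand].sum()))
    return counts


def random_model(
    obs: PartialObservation,
    k_per_layer: list[int],
    rng_seed: int | np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Uniformly random binary classifier baseline.

    Per layer, exactly ``k`` candidate pairs are predicted as links, chosen
    uniformly without replacement.  Returns strictly-upper-triangular
    boolean matrices.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    preds = []
    for lid, k in zip(obs.layer_ids, k_per_layer):
        cand = unobserved_pair_mask(obs, lid)
        ii, jj = np.nonzero(cand)
        if not 0 <= k <= ii.size:
            raise ValueError(f"layer {lid}: k={k} outside [0, {ii.size}]")
        pick = rng.choice(ii.size, size=k, replace=False)
        pred = np.zeros_like(cand)
        pred[ii[pick], jj[pick]] = True
        preds.append(pred)
    return preds


def binarize_topk(p: np.ndarray, candidate_mask: np.ndarray, k: int) -> np.ndarray:
    """Predict the ``k`` highest-probability candidate pairs as links.

    Ties at the cutoff break by canonical (row-major i<j) pair order, so the
    output is deterministic and has exactly ``k`` positives.
    """
    ii, jj = np.nonzero(candidate_mask)  # row-major == canonical order
    if not 0 <= k <= ii.size:
        raise ValueError(f"k={k} outside [0, {ii.size}]")
    scores = p[ii, jj]
    top = np.argsort(-scores, kind="stable")[:k]
    pred = np.zeros_like(candidate_mask, dtype=bool)
    pred[ii[top], jj[top]] = True
    return pred


def binarize_threshold(p: np.ndarray, candidate_mask: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Predict a link wherever the candidate probability reaches the threshold."""
    return candidate_mask & (p >= threshold)


def confusion(
    truth: np.ndarray, pred: np.ndarray, eval_mask: np.ndarray
) -> ConfusionCounts:
    """Confusion counts of a binary prediction over the masked i<j pairs."""
    sel = np.triu(eval_mask, k=1)
    t = truth[sel].astype(bool)
    q = pred[sel].astype(bool)
    return ConfusionCounts(
        tp=int((t & q).sum()),
        tn=int((~t & ~q).sum()),
        fp=int((~t & q).sum()),
        fn=int((t & ~q).sum()),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 when the denominator
    vanishes (any empty predicted or actual class)."""
    num = c.tp * c.tn - c.fp * c.fn
    den = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if den == 0:
        return 0.0
    return num / math.sqrt(den)


def gmean(c: ConfusionCounts) -> float:
    """sqrt(recall * specificity); NaN when either class is empty (the
    metric is undefined and must be excluded from averages)."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        return float("nan")
    recall = c.tp / (c.tp + c.fn)
    specificity = c.tn / (c.tn + c.fp)
    return math.sqrt(recall * specificity)


def evaluate_reconstruction(
    truth: MultiplexNetwork,
    predictions: list[np.ndarray],
    obs: PartialObservation,
) -> dict[str, ConfusionCounts]:
    """Per-layer and pooled confusion counts over the unobserved region.

    ``predictions`` are per-layer boolean matrices (upper-triangular or
    symmetric; only i<j candidate entries are read).  The pooled counts sum
    the per-layer counts and appear under the key ``"all"``.
    """
    out: dict[str, ConfusionCounts] = {}
    pooled = ConfusionCounts()
    for lid, a, pred in zip(truth.layer_ids, truth.adjacency, predictions):
        cand = unobserved_pair_mask(obs, lid)
        cc = confusion(a, pred, cand)
        out[lid] = cc
        pooled = pooled + cc
    out["all"] = pooled
    return out
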