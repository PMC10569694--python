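"""Scoring of machine counts against ground truth or a reference labeling.

Instance matching is one-to-one, either by centroid distance (greedy,
closest pairs first; default tolerance = mean nucleus radius derived from
the reference volumes) or by voxel overlap (greedy by IoU, default
threshold 0.3). Precision/recall/F1 follow from the match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .instances import InstanceLabels
from .phantom import GroundTruth

__all__ = ["MatchResult", "match_instances", "f1", "mean_radius_um"]


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int]] = field(default_factory=list)  # (pred ID, truth ID)
    criterion: str = "centroid"
    tol: float = float("nan")

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("TP/FP/FN must be non-negative")
        if self.tp != len(self.pairs):
            raise ValueError("TP must equal the number of matched pairs")


def mean_radius_um(volumes_um3: np.ndarray) -> float:
    """Mean equivalent-sphere radius of a set of instance volumes."""
    v = np.asarray(volumes_um3, dtype=float)
    v = v[v > 0]
    if v.size == 0:
        raise ValueError("no positive volumes to derive a radius from")
    return float(np.mean((3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)))


def _truth_fields(truth) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(truth, GroundTruth):
        return truth.labels, truth.centroids_um, truth.volumes_um3
    if isinstance(truth, InstanceLabels):
        return truth.labels, truth.centroids_um, truth.volumes_um3
    raise TypeError(f"unsupported truth type {type(truth)!r}")


def _match_centroid(pred_c, truth_c, tol) -> list[tuple[int, int]]:
    if len(pred_c) == 0 or len(truth_c) == 0:
        return []
    d = np.linalg.norm(pred_c[:, None, :] - truth_c[None, :, :], axis=2)
    pi, ti = np.nonzero(d <= tol)
    order = np.argsort(d[pi, ti], kind="stable")
    pairs: list[tuple[int, int]] = []
    used_p: set[int] = set()
    used_t: set[int] = set()
    for k in order:
        p, t = int(pi[k]), int(ti[k])
        if p in used_p or t in used_t:
            continue
        used_p.add(p)
        used_t.add(t)
        pairs.append((p + 1, t + 1))
    return pairs


def _match_overlap(pred_labels, truth_labels, tol) -> list[tuple[int, int]]:
    both = (pred_labels > 0) & (truth_labels > 0)
    if not both.any():
        return []
    np_pred = int(pred_labels.max())
    nt = int(truth_labels.max())
    pair_idx = pred_labels[both].astype(np.int64) * (nt + 1) + truth_labels[both].astype(np.int64)
    inter_counts = np.bincount(pair_idx, minlength=(np_pred + 1) * (nt + 1))
    pred_sizes = np.bincount(pred_labels.ravel(), minlength=np_pred + 1)
    truth_sizes = np.bincount(truth_labels.ravel(), minlength=nt + 1)
    nz = np.nonzero(inter_counts)[0]
    p_ids, t_ids = nz // (nt + 1), nz % (nt + 1)
    inter = inter_counts[nz].astype(float)
    union = pred_sizes[p_ids] + truth_sizes[t_ids] - inter
    iou = inter / union
    order = np.argsort(-iou, kind="stable")
    pairs: list[tuple[int, int]] = []
    used_p: set[int] = set()
    used_t: set[int] = set()
    for k in order:
        if iou[k] < tol:
            break
        p, t = int(p_ids[k]), int(t_ids[k])
        if p in used_p or t in used_t:
            continue
        used_p.add(p)
        used_t.add(t)
        pairs.append((p, t))
    return pairs


def match_instances(
    pred: InstanceLabels,
    truth,
    criterion: str = "centroid",
    tol: float | None = None,
) -> MatchResult:
    """One-to-one matching of predicted to reference instances.

    criterion='centroid': greedy nearest-neighbor on physical centroid
    distance, closest pairs first, distance <= tol (default: the mean
    nucleus radius of the reference). criterion='overlap': match iff
    intersection-over-union >= tol (default 0.3), largest IoU first.
    """
    truth_labels, truth_c, truth_v = _truth_fields(truth)
    if pred.labels.shape != truth_labels.shape:
        raise ValueError(
            f"grid geometry mismatch: pred {pred.labels.shape} vs truth {truth_labels.shape}"
        )
    n_truth = len(truth_c)
    if criterion == "centroid":
        if tol is None:
            tol = mean_radius_um(truth_v)
        pairs = _match_centroid(pred.centroids_um, truth_c, tol)
    elif criterion == "overlap":
        if tol is None:
            tol = 0.3
        pairs = _match_overlap(pred.labels, truth_labels, tol)
    else:
        raise ValueError("criterion must be 'centroid' or 'overlap'")
    tp = len(pairs)
    return MatchResult(
        tp=tp,
        fp=pred.count - tp,
        fn=n_truth - tp,
        pairs=pairs,
        criterion=criterion,
        tol=float(tol),
    )


def f1(match: MatchResult) -> tuple[float, float, float]:
    """(precision, recall, F1); all zeros — with a warning — when nothing
    was predicted or annotated."""
    tp, fp, fn = match.tp, match.fp, match.fn
    if tp + fp + fn == 0:
        warnings.warn("match result is empty; returning (0, 0, 0)", stacklevel=2)
        return (0.0, 0.0, 0.0)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    score = 2 * p * r / (p + r) if p + r else 0.0
    return (p, r, score)
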