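"""Severity labeling, classification metrics, and timing bookkeeping.

Clusters are mapped to severity levels by their mean trunk displacement
(lowest displacement = mildest), predicted levels are compared against
FMA-UE-derived reference categories, and the federated run's cost is
decomposed into CompT (slowest client) + CmT (server aggregation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import ConfigurationError, EvaluationError, InputError

FMA_MAX = 66.0


def severity_level_names(k: int) -> tuple[str, ...]:
    if k == 2:
        return ("mild", "severe")
    if k == 3:
        return ("mild", "moderate", "severe")
    return tuple(f"severity_{i}" for i in range(k))


@dataclass(frozen=True)
class EvalReport:
    """Support-weighted classification metrics plus the confusion matrix.

    ``accuracy``/``precision``/``recall``/``f_score`` are proportions in
    [0, 1]; ``per_class`` maps each category to its own (precision, recall,
    F, support) tuple.  With support weighting, weighted recall equals
    accuracy by identity.
    """

    accuracy: float
    precision: float
    recall: float
    f_score: float
    confusion: np.ndarray
    per_class: dict
    n: int
    labels: tuple


@dataclass(frozen=True)
class TimingReport:
    comp_time_s: float
    comm_time_s: float
    total_s: float


def fma_category(
    score: float,
    k: int,
    severe_boundary: float = 29.0,
    mild_boundary: float = 43.0,
) -> int:
    """Map an FMA-UE score to a severity level index (0 = mildest).

    The severe cutoff of 29 is the clinically anchored boundary (scores
    below 29 denote severe impairment); for k=3 the moderate/mild split
    defaults to 43 and is an explicit assumption, configurable here.  The
    boundaries are half-open: a score exactly at a boundary falls in the
    milder category.
    """
    if not 0.0 <= score <= FMA_MAX:
        raise InputError(f"FMA-UE score {score} outside [0, {FMA_MAX}]")
    if k == 2:
        return 0 if score >= severe_boundary else 1
    if k == 3:
        if score >= mild_boundary:
            return 0
        if score >= severe_boundary:
            return 1
        return 2
    raise ConfigurationError("fma_category supports k in {2, 3}")


def severity_map_from_td(labels, cluster_or_member_td, k: int | None = None) -> np.ndarray:
    """Rank clusters by mean trunk displacement of their members.

    Returns ``rank`` with ``rank[c]`` the severity level of cluster ``c``
    (0 = mildest = lowest mean TD).  Ties break toward the lower cluster
    index.  Every cluster in [0, k) must be non-empty.
    """
    labels = np.asarray(labels)
    td = np.asarray(cluster_or_member_td, dtype=float)
    if k is None:
        k = int(labels.max()) + 1
    if len(td) != len(labels):
        raise InputError("per-member trunk displacements must align with labels")
    means = np.empty(k)
    for c in range(k):
        mask = labels == c
        if not mask.any():
            raise EvaluationError(f"cluster {c} is empty")
        means[c] = td[mask].mean()
    order = np.argsort(means, kind="stable")
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    return rank


def score(predicted, reference) -> EvalReport:
    """Confusion matrix and support-weighted precision/recall/F.

    Per-class precision, recall and F (harmonic mean) are combined by
    weighting with each reference class's support; accuracy is the
    confusion-matrix trace over n.
    """
    pred = np.asarray(predicted)
    ref = np.asarray(reference)
    if pred.shape != ref.shape:
        raise InputError("predicted and reference label vectors differ in length")
    cats = tuple(sorted(set(ref.tolist()) | set(pred.tolist())))
    conf = _sk_confusion(ref, pred, labels=list(cats))
    n = int(conf.sum())
    accuracy = float(np.trace(conf)) / n

    per_class = {}
    weighted = np.zeros(3)
    for i, cat in enumerate(cats):
        tp = conf[i, i]
        support = conf[i, :].sum()
        pred_c = conf[:, i].sum()
        prec = tp / pred_c if pred_c else 0.0
        rec = tp / support if support else 0.0
        f = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        per_class[cat] = {
            "precision": float(prec),
            "recall": float(rec),
            "f_score": float(f),
            "support": int(support),
        }
        weighted += support / n * np.array([prec, rec, f])
    return EvalReport(
        accuracy=accuracy,
        precision=float(weighted[0]),
        recall=float(weighted[1]),
        f_score=float(weighted[2]),
        confusion=conf,
        per_class=per_class,
        n=n,
        labels=cats,
    )


def timing(summaries, comm_time_s: float) -> TimingReport:
    """CompT = slowest client, CmT = aggregation, total = CompT + CmT."""
    times = [
        s.comp_time_s if hasattr(s, "comp_time_s") else float(s) for s in summaries
    ]
    if not times:
        raise InputError("need at least one client summary")
    if comm_time_s < 0 or any(t < 0 for t in times):
        raise InputError("times must be nonnegative")
    comp = float(max(times))
    return TimingReport(
        comp_time_s=comp, comm_time_s=float(comm_time_s), total_s=comp + float(comm_time_s)
    )
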