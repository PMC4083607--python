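"""Residue-level and epitope-level evaluation, plus the LOOCV driver.

Residue-level metrics from the confusion counts at a score threshold:

    ACC = (TP+TN)/(TP+TN+FP+FN),  SN = TP/(TP+FN),
    SP  = TN/(TN+FP),             F  = 2·TP/(2·TP+FN+FP),

plus the ROC AUC over the residue scores. Epitope-level metrics compare
predicted clusters with observed epitopes: an observed epitope counts as
correctly predicted when a (one-to-one matched) predicted cluster covers
strictly more than 30% of its residues; an antigen is correct when every
observed epitope is matched and the predicted cluster count equals the
observed epitope count. Aggregated over the evaluation set,

    V_site = (# correctly predicted epitopes) / (# predicted epitopes),
    V_p    = (# correctly predicted antigens) / (# antigens).

Cross-validation is leave-one-antigen-out: each chain is held out in
turn, the predictor is trained on the rest, and performance is the
unweighted mean of per-antigen AUCs (pooled residue metrics are also
reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "ResidueMetrics",
    "EpitopeMetrics",
    "confusion_counts",
    "residue_metrics",
    "match_epitopes",
    "epitope_metrics",
    "LoocvReport",
    "leave_one_antigen_out",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ResidueMetrics:
    """ACC/SN/SP/F at a threshold plus AUC; undefined values are ``None``."""

    counts: ConfusionCounts
    acc: float | None
    sn: float | None
    sp: float | None
    f: float | None
    auc: float | None

    def as_dict(self) -> dict:
        return {
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "fn": self.counts.fn,
            "acc": self.acc,
            "sn": self.sn,
            "sp": self.sp,
            "f": self.f,
            "auc": self.auc,
        }


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def confusion_counts(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.0
) -> ConfusionCounts:
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same shape")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )


def metrics_from_counts(counts: ConfusionCounts, auc: float | None = None) -> ResidueMetrics:
    """Closed-form metrics from confusion counts (zero denominators -> None)."""
    return ResidueMetrics(
        counts=counts,
        acc=_ratio(counts.tp + counts.tn, counts.total),
        sn=_ratio(counts.tp, counts.tp + counts.fn),
        sp=_ratio(counts.tn, counts.tn + counts.fp),
        f=_ratio(2 * counts.tp, 2 * counts.tp + counts.fn + counts.fp),
        auc=auc,
    )


def residue_metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.0
) -> ResidueMetrics:
    """Residue-level metrics at ``threshold`` plus rank-based AUC.

    Ties in scores are handled by midranks (standard ROC AUC). With a
    single-class label vector the AUC is undefined and reported as
    ``None``, as is any metric with a zero denominator.
    """
    labels = np.asarray(labels).astype(int)
    counts = confusion_counts(labels, scores, threshold)
    auc = None
    if np.unique(labels).size == 2:
        auc = float(roc_auc_score(labels, scores))
    return metrics_from_counts(counts, auc)


# ---------------------------------------------------------------------------
# Epitope-level metrics


@dataclass
class AntigenMatchResult:
    """Match outcome for one antigen."""

    n_predicted: int
    n_observed: int
    n_matched: int  # observed epitopes matched by a distinct cluster
    matches: list[tuple[int, int, float]]  # (cluster idx, epitope id, coverage)
    correct: bool


@dataclass
class EpitopeMetrics:
    v_site: float | None
    v_p: float | None
    per_antigen: dict[str, AntigenMatchResult] = field(default_factory=dict)


def match_epitopes(
    predicted: Sequence[Iterable[int]],
    observed: Mapping[int, Iterable[int]],
    min_coverage: float = 0.30,
) -> AntigenMatchResult:
    """Greedy one-to-one matching of predicted clusters to observed epitopes.

    Candidate pairs are ordered by descending coverage fraction
    |cluster ∩ epitope| / |epitope| and matched greedily, each cluster and
    each epitope at most once; a pair counts only when its coverage is
    strictly greater than ``min_coverage``. The antigen is correct iff
    every observed epitope is matched *and* the number of predicted
    clusters equals the number of observed epitopes.
    """
    pred_sets = [frozenset(int(i) for i in cl) for cl in predicted]
    obs_sets = {int(k): frozenset(int(i) for i in v) for k, v in observed.items()}
    if any(len(s) == 0 for s in obs_sets.values()):
        raise ValueError("observed epitopes must be non-empty")

    candidates = []
    for ci, cl in enumerate(pred_sets):
        for eid, ep in obs_sets.items():
            cov = len(cl & ep) / len(ep)
            if cov > min_coverage:
                candidates.append((cov, ci, eid))
    # descending coverage; deterministic tie-break by cluster then epitope
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    used_clusters: set[int] = set()
    used_epitopes: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for cov, ci, eid in candidates:
        if ci in used_clusters or eid in used_epitopes:
            continue
        used_clusters.add(ci)
        used_epitopes.add(eid)
        matches.append((ci, eid, cov))

    n_matched = len(matches)
    correct = n_matched == len(obs_sets) and len(pred_sets) == len(obs_sets)
    return AntigenMatchResult(
        n_predicted=len(pred_sets),
        n_observed=len(obs_sets),
        n_matched=n_matched,
        matches=matches,
        correct=correct,
    )


def epitope_metrics(
    per_antigen: Mapping[str, tuple[Sequence[Iterable[int]], Mapping[int, Iterable[int]]]],
    min_coverage: float = 0.30,
) -> EpitopeMetrics:
    """Aggregate V_site and V_p over an evaluation set.

    ``per_antigen`` maps chain id to (predicted clusters, observed
    epitopes). Antigens with zero predicted clusters contribute nothing to
    the V_site denominator and count as incorrectly predicted antigens.
    """
    results: dict[str, AntigenMatchResult] = {}
    total_pred = total_matched = total_correct = 0
    for chain_id, (pred, obs) in per_antigen.items():
        res = match_epitopes(pred, obs, min_coverage)
        results[chain_id] = res
        total_pred += res.n_predicted
        total_matched += res.n_matched
        total_correct += int(res.correct)
    return EpitopeMetrics(
        v_site=_ratio(total_matched, total_pred),
        v_p=_ratio(total_correct, len(results)),
        per_antigen=results,
    )


# ---------------------------------------------------------------------------
# Leave-one-antigen-out cross-validation


@dataclass
class LoocvReport:
    """Per-antigen scores and metrics from leave-one-antigen-out CV."""

    per_antigen_auc: dict[str, float | None]
    mean_auc: float | None  # unweighted mean over antigens with defined AUC
    pooled: ResidueMetrics  # residue-pooled counts + pooled AUC
    scores: dict[str, np.ndarray]  # held-out fused score per residue
    predictions: dict[str, np.ndarray]  # held-out binary class per residue


def leave_one_antigen_out(
    features: Mapping[str, np.ndarray],
    labels: Mapping[str, np.ndarray],
    make_classifier: Callable[[], object],
) -> LoocvReport:
    """Leave-one-antigen-out cross-validation of a residue classifier.

    For each antigen the classifier from ``make_classifier()`` is fitted
    on all remaining antigens' residues and scores the held-out chain.
    Per-antigen AUCs come from ``decision_function``; the pooled confusion
    counts come from ``predict``. Held-out chains whose labels are
    single-class have no defined AUC and are excluded from the mean with a
    log entry.
    """
    ids = list(features)
    if len(ids) < 2:
        raise ValueError("leave-one-antigen-out needs >= 2 antigens")
    if set(ids) != set(labels):
        raise ValueError("features and labels must cover the same antigens")

    per_auc: dict[str, float | None] = {}
    scores: dict[str, np.ndarray] = {}
    preds: dict[str, np.ndarray] = {}
    for held in ids:
        rest = [i for i in ids if i != held]
        X_tr = np.vstack([features[i] for i in rest])
        y_tr = np.concatenate([labels[i] for i in rest])
        clf = make_classifier()
        clf.fit(X_tr, y_tr)
        s = np.asarray(clf.decision_function(features[held]), dtype=float)
        scores[held] = s
        preds[held] = np.asarray(clf.predict(features[held])).astype(int)
        y_h = np.asarray(labels[held]).astype(int)
        if np.unique(y_h).size == 2:
            per_auc[held] = float(roc_auc_score(y_h, s))
        else:
            logger.info("antigen %s has single-class labels; AUC undefined", held)
            per_auc[held] = None

    defined = [v for v in per_auc.values() if v is not None]
    mean_auc = float(np.mean(defined)) if defined else None
    all_y = np.concatenate([np.asarray(labels[i]).astype(int) for i in ids])
    all_s = np.concatenate([scores[i] for i in ids])
    all_p = np.concatenate([preds[i] for i in ids])
    counts = ConfusionCounts(
        tp=int(((all_p == 1) & (all_y == 1)).sum()),
        fp=int(((all_p == 1) & (all_y == 0)).sum()),
        tn=int(((all_p == 0) & (all_y == 0)).sum()),
        fn=int(((all_p == 0) & (all_y == 1)).sum()),
    )
    auc = float(roc_auc_score(all_y, all_s)) if np.unique(all_y).size == 2 else None
    pooled = metrics_from_counts(counts, auc)
    return LoocvReport(
        per_antigen_auc=per_auc,
        mean_auc=mean_auc,
        pooled=pooled,
        scores=scores,
        predictions=preds,
    )
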