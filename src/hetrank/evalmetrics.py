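"""Ranking and classification metrics.

Conventions (stated so results are reproducible): NDCG uses binary gain
2^rel - 1 with discount log2(position + 1); a query with no relevant item
contributes 0 to NDCG/MRR/MAP.  Score ties are ranked by candidate id; AUC
uses the tie-corrected Mann-Whitney statistic so id order does not affect
it.  ROCk truncates each query's ranked list at rank k, builds the ROC over
the truncated list with TPR/FPR normalised by the query's total
positives/negatives, and normalises the area by the maximum achievable
area at that k; queries where the maximum area is zero contribute 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class LabeledRanking:
    """One query's candidates ordered by descending score (ties by id)."""

    qid: str
    dids: list[str]
    labels: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        order = sorted(
            range(len(self.dids)), key=lambda i: (-self.scores[i], self.dids[i])
        )
        self.dids = [self.dids[i] for i in order]
        self.labels = self.labels[order]
        self.scores = self.scores[order]


@dataclass
class MetricReport:
    scope: str  # per_query | macro_mean | pooled
    values: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"scope": self.scope, **self.values}, fh, indent=2)


def _dcg(labels: np.ndarray, k: int | None = None) -> float:
    lab = labels[:k] if k is not None else labels
    gains = 2.0**lab - 1.0
    disc = 1.0 / np.log2(np.arange(len(lab)) + 2.0)
    return float((gains * disc).sum())


def ndcg_at_k(r: LabeledRanking, k: int | None = None) -> float:
    """NDCG@k; k=None uses the full list length."""
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    if r.labels.sum() == 0:
        return 0.0
    ideal = np.sort(r.labels)[::-1]
    idcg = _dcg(ideal, k)
    return _dcg(r.labels, k) / idcg if idcg > 0 else 0.0


def ndcg(r: LabeledRanking) -> float:
    return ndcg_at_k(r, None)


def reciprocal_rank(r: LabeledRanking) -> float:
    hits = np.where(r.labels > 0)[0]
    return 1.0 / (hits[0] + 1) if len(hits) else 0.0


def mrr(rankings: list[LabeledRanking]) -> float:
    if not rankings:
        raise ValueError("need at least one query")
    return float(np.mean([reciprocal_rank(r) for r in rankings]))


def average_precision(r: LabeledRanking) -> float:
    rel = r.labels > 0
    if not rel.any():
        return 0.0
    cum = np.cumsum(rel)
    prec = cum[rel] / (np.where(rel)[0] + 1)
    return float(prec.mean())


def mean_ap(rankings: list[LabeledRanking]) -> float:
    if not rankings:
        raise ValueError("need at least one query")
    return float(np.mean([average_precision(r) for r in rankings]))


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve (tie-corrected Mann-Whitney statistic)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def aupr(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve (step integration)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUPR needs both classes present")
    return float(average_precision_score(labels, scores))


def roc_k_query(r: LabeledRanking, k: int) -> float:
    """ROC area over the top-k ranked candidates of one query, normalised
    by the maximum area achievable at that truncation."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n_pos = int((r.labels > 0).sum())
    n_neg = len(r.labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return 0.0
    top = r.labels[:k]
    area = 0.0
    tpr = 0.0
    for lab in top:
        if lab > 0:
            tpr += 1.0 / n_pos
        else:
            area += tpr / n_neg
    k_eff = min(k, len(r.labels))
    best_pos = min(n_pos, k_eff)
    best_neg = k_eff - best_pos
    max_area = (best_pos / n_pos) * (best_neg / n_neg)
    return area / max_area if max_area > 0 else 0.0


def roc_k(rankings: list[LabeledRanking], k: int) -> float:
    """Macro-averaged ROCk over queries."""
    if not rankings:
        raise ValueError("need at least one query")
    return float(np.mean([roc_k_query(r, k) for r in rankings]))


# ---------------------------------------------------------------------------
# run-level aggregation
# ---------------------------------------------------------------------------

def query_metrics(r: LabeledRanking, ndcg_k: int = 10) -> dict[str, float]:
    return {
        f"NDCG@{ndcg_k}": ndcg_at_k(r, ndcg_k),
        "NDCG": ndcg(r),
        "RR": reciprocal_rank(r),
        "AP": average_precision(r),
    }


def evaluate_fold(
    rankings: list[LabeledRanking], ndcg_k: int = 10
) -> dict[str, MetricReport]:
    """Macro (per-query mean) and pooled (all pairs) views for one fold."""
    labels = np.concatenate([r.labels for r in rankings])
    scores = np.concatenate([r.scores for r in rankings])
    pooled = MetricReport(scope="pooled")
    if len(np.unique(labels)) == 2:
        pooled.values["AUC"] = auc(labels, scores)
        pooled.values["AUPR"] = aupr(labels, scores)
    macro = MetricReport(
        scope="macro_mean",
        values={
            f"NDCG@{ndcg_k}": float(
                np.mean([ndcg_at_k(r, ndcg_k) for r in rankings])
            ),
            "NDCG": float(np.mean([ndcg(r) for r in rankings])),
            "MRR": mrr(rankings),
            "MAP": mean_ap(rankings),
        },
    )
    per_query = MetricReport(
        scope="per_query",
        values={
            r.qid: ndcg_at_k(r, ndcg_k) for r in rankings
        },
    )
    return {"pooled": pooled, "macro_mean": macro, "per_query": per_query}


def evaluate_run(
    fold_rankings: list[list[LabeledRanking]], ndcg_k: int = 10
) -> dict[str, MetricReport]:
    """Average fold-level reports across folds (the headline numbers) and
    attach a per-cancer view pooled over folds.

    ``fold_rankings`` must contain one entry per fold; a missing (empty)
    fold is an error.
    """
    if not fold_rankings or any(not f for f in fold_rankings):
        raise ValueError("every fold must provide rankings")
    fold_reports = [evaluate_fold(f, ndcg_k) for f in fold_rankings]
    out: dict[str, MetricReport] = {}
    for scope in ("pooled", "macro_mean"):
        keys = sorted({k for fr in fold_reports for k in fr[scope].values})
        out[scope] = MetricReport(
            scope=scope,
            values={
                k: float(
                    np.mean(
                        [fr[scope].values[k] for fr in fold_reports if k in fr[scope].values]
                    )
                )
                for k in keys
            },
        )
    # per-cancer AUC pooled over all folds' test pairs
    by_cancer: dict[str, tuple[list[float], list[float]]] = {}
    for fold in fold_rankings:
        for r in fold:
            for did, lab, sc in zip(r.dids, r.labels, r.scores):
                by_cancer.setdefault(did, ([], []))[0].append(lab)
                by_cancer.setdefault(did, ([], []))[1].append(sc)
    per_cancer = {}
    for did, (labs, scs) in by_cancer.items():
        if len(np.unique(labs)) == 2:
            per_cancer[did] = auc(np.array(labs), np.array(scs))
    out["per_cancer"] = MetricReport(scope="per_query", values=per_cancer)
    if per_cancer:
        out["pooled"].values["per_cancer_median_AUC"] = float(
            np.median(list(per_cancer.values()))
        )
    return out


def report_table(reports: dict[str, MetricReport]) -> pd.DataFrame:
    rows = [
        {"scope": name, "metric": k, "value": v}
        for name, rep in reports.items()
        for k, v in rep.values.items()
    ]
    return pd.DataFrame(rows)
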