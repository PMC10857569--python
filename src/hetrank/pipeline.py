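"""End-to-end orchestration: features -> searched GNN -> edge embeddings ->
LambdaMART ranking -> metrics, under either cross-validation scenario."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autognn import GnnConfig, SearchSpace, search
from .evalmetrics import LabeledRanking, evaluate_fold
from .features import node_attribute_features
from .hetnet import (
    CandidatePairSet,
    HeteroNetwork,
    NodeType,
    Relation,
    enumerate_candidate_pairs,
)
from .ranker import (
    LambdaMartConfig,
    RankingDataset,
    RankingSample,
    predict_scores,
    train_lambdamart,
)
from .splits import (
    FoldAssignment,
    SCENARIO_KNOWN,
    SCENARIO_NOVEL,
    grouped_query_folds,
    mask_test_edges,
    within_query_folds,
)

logger = logging.getLogger("hetrank")


@dataclass
class PipelineConfig:
    query_type: NodeType = NodeType.CIRCRNA
    scenario: str = SCENARIO_KNOWN
    n_folds: int = 5
    folds: list[int] | None = None  # None = all folds
    seed: int = 0
    gnn: GnnConfig = field(default_factory=GnnConfig)
    space: SearchSpace = field(default_factory=SearchSpace)
    ranker: LambdaMartConfig = field(default_factory=LambdaMartConfig)
    ndcg_k: int = 10
    stratify: bool = True  # known-query scenario only


def make_folds(pairs: CandidatePairSet, cfg: PipelineConfig) -> FoldAssignment:
    if cfg.scenario == SCENARIO_NOVEL:
        return grouped_query_folds(pairs, cfg.n_folds, cfg.seed)
    if cfg.scenario == SCENARIO_KNOWN:
        return within_query_folds(pairs, cfg.n_folds, cfg.seed,
                                  stratify=cfg.stratify)
    raise ValueError(f"unknown scenario {cfg.scenario!r}")


def ranking_dataset_from_embeddings(
    pairs: CandidatePairSet, vectors: np.ndarray, indices: np.ndarray
) -> RankingDataset:
    samples = [
        RankingSample(
            label=pairs.pairs[i][2],
            qid=pairs.pairs[i][0].id,
            features=vectors[i],
            did=pairs.pairs[i][1].id,
        )
        for i in indices
    ]
    return RankingDataset(samples=samples)


def _labeled_rankings(
    ranked_lists, dataset: RankingDataset
) -> list[LabeledRanking]:
    label_of = {(s.qid, s.did): s.label for s in dataset.samples}
    out = []
    for rl in ranked_lists:
        dids = [d for d, _ in rl.ranking]
        out.append(
            LabeledRanking(
                qid=rl.qid,
                dids=dids,
                labels=np.array([label_of[(rl.qid, d)] for d in dids], dtype=float),
                scores=np.array([s for _, s in rl.ranking]),
            )
        )
    return out


def degree_baseline_rankings(
    train_net: HeteroNetwork,
    pairs: CandidatePairSet,
    test_idx: np.ndarray,
) -> list[LabeledRanking]:
    """Popularity baseline: a candidate cancer's score is its degree in the
    training network's task relation."""
    rel = (
        Relation.CIRC_CANCER
        if pairs.query_type is NodeType.CIRCRNA
        else Relation.DRUG_CANCER
    )
    deg = {
        c: len(train_net.neighbors(c, rel))
        for c in train_net.nodes_by_type[NodeType.CANCER]
    }
    by_query: dict = {}
    for i in test_idx:
        q, c, lab = pairs.pairs[i]
        by_query.setdefault(q.id, []).append((c.id, float(deg.get(c, 0)), lab))
    out = []
    for qid, items in by_query.items():
        out.append(
            LabeledRanking(
                qid=qid,
                dids=[c for c, _, _ in items],
                labels=np.array([l for _, _, l in items], dtype=float),
                scores=np.array([s for _, s, _ in items]),
            )
        )
    return out


@dataclass
class FoldResult:
    fold: int
    metrics: dict
    baseline_metrics: dict
    architecture: dict


def run_fold(
    net: HeteroNetwork,
    pairs: CandidatePairSet,
    folds: FoldAssignment,
    fold_idx: int,
    cfg: PipelineConfig,
) -> FoldResult:
    train_net = mask_test_edges(net, folds, fold_idx)
    # profiles and message passing over the full node universe but with
    # training-fold edges only (masked nodes keep a degree-0 slot)
    feats = node_attribute_features(train_net, cfg.query_type, universe=net)
    arch, model, _ = search(
        train_net, feats, cfg.space, cfg.gnn, query_type=cfg.query_type,
        universe=net,
    )
    table = model.embed_edges(pairs)
    train_idx = folds.train_indices(fold_idx)
    test_idx = folds.test_indices(fold_idx)
    train_ds = ranking_dataset_from_embeddings(pairs, table.vectors, train_idx)
    test_ds = ranking_dataset_from_embeddings(pairs, table.vectors, test_idx)
    ensemble = train_lambdamart(train_ds, cfg.ranker)
    ranked = predict_scores(ensemble, test_ds)
    rankings = _labeled_rankings(ranked, test_ds)
    reports = evaluate_fold(rankings, cfg.ndcg_k)
    baseline = degree_baseline_rankings(train_net, pairs, test_idx)
    base_reports = evaluate_fold(baseline, cfg.ndcg_k)
    return FoldResult(
        fold=fold_idx,
        metrics={
            **reports["pooled"].values,
            **reports["macro_mean"].values,
        },
        baseline_metrics={
            **base_reports["pooled"].values,
            **base_reports["macro_mean"].values,
        },
        architecture=arch.to_table(),
    )


def run_pipeline(net: HeteroNetwork, cfg: PipelineConfig) -> dict:
    """Run the chosen scenario and average metrics across the folds run."""
    pairs = enumerate_candidate_pairs(net, cfg.query_type)
    folds = make_folds(pairs, cfg)
    fold_ids = cfg.folds if cfg.folds is not None else list(range(cfg.n_folds))
    results = [run_fold(net, pairs, folds, i, cfg) for i in fold_ids]
    keys = sorted({k for r in results for k in r.metrics})
    bkeys = sorted({k for r in results for k in r.baseline_metrics})
    return {
        "scenario": cfg.scenario,
        "query_type": cfg.query_type.value,
        "folds_run": fold_ids,
        "metrics": {
            k: float(np.mean([r.metrics[k] for r in results if k in r.metrics]))
            for k in keys
        },
        "baseline_metrics": {
            k: float(
                np.mean(
                    [r.baseline_metrics[k] for r in results if k in r.baseline_metrics]
                )
            )
            for k in bkeys
        },
        "per_fold": [
            {
                "fold": r.fold,
                "metrics": r.metrics,
                "baseline_metrics": r.baseline_metrics,
                "architecture": r.architecture,
            }
            for r in results
        ],
    }
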