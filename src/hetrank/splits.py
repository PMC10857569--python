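"""Cross-validation protocols for the two application scenarios.

* novel-query — queries (circRNAs or drugs) are partitioned into folds;
  all samples of a query share its fold, so train and test query ids never
  intersect;
* known-query — samples are randomly partitioned, stratified per query so
  every query with enough samples contributes to both train and test.

``mask_test_edges`` removes the test fold's observed query-cancer edges
from the network used for feature computation and GNN training (leakage
control); cross-type edges not under evaluation (e.g. circRNA-drug) are
retained, which is what keeps novel queries connected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hetnet import (
    CandidatePairSet,
    HeteroNetwork,
    NodeType,
    Relation,
    build_network,
)

logger = logging.getLogger("hetrank")

SCENARIO_NOVEL = "novel_query"
SCENARIO_KNOWN = "known_query"


@dataclass
class FoldAssignment:
    n_folds: int
    scenario: str
    seed: int
    fold_of: np.ndarray  # fold index per sample (position in pairs.pairs)
    pairs: CandidatePairSet

    def __post_init__(self) -> None:
        counts = np.bincount(self.fold_of, minlength=self.n_folds)
        if (counts == 0).any():
            raise ValueError("every fold must be non-empty")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.where(self.fold_of == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.where(self.fold_of != fold)[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "query_id": [q.id for q, _, _ in self.pairs.pairs],
                "cancer_id": [c.id for _, c, _ in self.pairs.pairs],
                "label": [l for _, _, l in self.pairs.pairs],
                "fold": self.fold_of,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def grouped_query_folds(
    pairs: CandidatePairSet, n_folds: int = 5, seed: int = 0
) -> FoldAssignment:
    """Scenario 1 (novel queries): partition query ids into folds."""
    qids = pairs.queries
    if len(qids) < n_folds:
        raise ValueError(f"{len(qids)} queries cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(qids))
    fold_of_qid = {qids[j]: i for i, chunk in
                   enumerate(np.array_split(perm, n_folds)) for j in chunk}
    fold_of = np.array([fold_of_qid[q] for q, _, _ in pairs.pairs], dtype=np.intp)
    return FoldAssignment(
        n_folds=n_folds, scenario=SCENARIO_NOVEL, seed=seed,
        fold_of=fold_of, pairs=pairs,
    )


def within_query_folds(
    pairs: CandidatePairSet, n_folds: int = 5, seed: int = 0,
    stratify: bool = True,
) -> FoldAssignment:
    """Scenario 2 (known queries): random sample partition, stratified per
    query by default so fold sizes within a query differ by at most 1."""
    if not pairs.pairs:
        raise ValueError("empty candidate pair set")
    rng = np.random.default_rng(seed)
    n = len(pairs.pairs)
    fold_of = np.empty(n, dtype=np.intp)
    if not stratify:
        perm = rng.permutation(n)
        for i, chunk in enumerate(np.array_split(perm, n_folds)):
            fold_of[chunk] = i
    else:
        by_query: dict = {}
        for i, (q, _, _) in enumerate(pairs.pairs):
            by_query.setdefault(q, []).append(i)
        for q, idx in by_query.items():
            idx = np.array(idx)
            rng.shuffle(idx)
            if len(idx) < n_folds:
                logger.info(
                    "query %s has %d sample(s) (< %d folds)", q.id, len(idx), n_folds
                )
            offset = int(rng.integers(n_folds))
            fold_of[idx] = (np.arange(len(idx)) + offset) % n_folds
    return FoldAssignment(
        n_folds=n_folds, scenario=SCENARIO_KNOWN, seed=seed,
        fold_of=fold_of, pairs=pairs,
    )


def mask_test_edges(
    net: HeteroNetwork, fold: FoldAssignment, fold_idx: int
) -> HeteroNetwork:
    """Training network for one fold: the test fold's positive query-cancer
    edges are removed; all other edges (including circRNA-drug) remain."""
    if not 0 <= fold_idx < fold.n_folds:
        raise ValueError(f"fold index {fold_idx} out of range")
    rel = (
        Relation.CIRC_CANCER
        if fold.pairs.query_type is NodeType.CIRCRNA
        else Relation.DRUG_CANCER
    )
    test_pos = {
        (fold.pairs.pairs[i][0], fold.pairs.pairs[i][1])
        for i in fold.test_indices(fold_idx)
        if fold.pairs.pairs[i][2] == 1
    }
    kept = [
        e
        for e in net.edges
        if not (e.relation == rel and (e.source, e.target) in test_pos)
    ]
    return build_network(kept)
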