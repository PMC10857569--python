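"""Tri-partite heterogeneous network assembly.

Nodes are circRNAs, drugs and cancers; edges fall into three relation
classes (circRNA-cancer, drug-cancer, circRNA-drug).  Edges are undirected
for message passing; the relation class is kept as edge metadata.  Isolated
nodes are pruned: the network contains exactly the nodes incident to at
least one edge.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("hetrank")


class NodeType(str, Enum):
    CIRCRNA = "circRNA"
    DRUG = "drug"
    CANCER = "cancer"


class Relation(str, Enum):
    CIRC_CANCER = "circ_cancer"
    DRUG_CANCER = "drug_cancer"
    CIRC_DRUG = "circ_drug"


#: endpoint node types implied by each relation (source type, target type)
RELATION_TYPES: dict[Relation, tuple[NodeType, NodeType]] = {
    Relation.CIRC_CANCER: (NodeType.CIRCRNA, NodeType.CANCER),
    Relation.DRUG_CANCER: (NodeType.DRUG, NodeType.CANCER),
    Relation.CIRC_DRUG: (NodeType.CIRCRNA, NodeType.DRUG),
}


@dataclass(frozen=True, order=True)
class NodeRef:
    """A typed node identifier; ``(id, node_type)`` is unique in a network."""

    id: str
    node_type: NodeType

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("node id must be non-empty")


@dataclass(frozen=True)
class TypedEdge:
    source: NodeRef
    target: NodeRef
    relation: Relation

    def __post_init__(self) -> None:
        want = RELATION_TYPES[self.relation]
        got = (self.source.node_type, self.target.node_type)
        if got != want:
            raise ValueError(
                f"edge {self.source.id}-{self.target.id}: endpoint types {got} "
                f"do not match relation {self.relation.value} (expects {want})"
            )
        if self.source == self.target:
            raise ValueError(f"self loop on {self.source.id}")


class HeteroNetwork:
    """Typed tri-partite graph with per-relation adjacency.

    Built from edges only, so every node has degree >= 1 by construction.
    """

    def __init__(self, edges: Iterable[TypedEdge]):
        edges = list(edges)
        if not edges:
            raise ValueError("cannot build a network from an empty edge list")
        seen: set[tuple[Relation, NodeRef, NodeRef]] = set()
        self.edges: list[TypedEdge] = []
        for e in edges:
            key = (e.relation, e.source, e.target)
            if key in seen:
                continue
            seen.add(key)
            self.edges.append(e)
        self.nodes_by_type: dict[NodeType, list[NodeRef]] = {t: [] for t in NodeType}
        node_set: set[NodeRef] = set()
        for e in self.edges:
            node_set.add(e.source)
            node_set.add(e.target)
        for n in sorted(node_set):
            self.nodes_by_type[n.node_type].append(n)
        # adjacency[node][relation] -> sorted neighbor list (undirected)
        self.adjacency: dict[NodeRef, dict[Relation, list[NodeRef]]] = {
            n: {} for n in node_set
        }
        for e in self.edges:
            self.adjacency[e.source].setdefault(e.relation, []).append(e.target)
            self.adjacency[e.target].setdefault(e.relation, []).append(e.source)
        for nbrs in self.adjacency.values():
            for rel in nbrs:
                nbrs[rel] = sorted(nbrs[rel])

    # -- basic accessors -------------------------------------------------
    @property
    def nodes(self) -> list[NodeRef]:
        return [n for t in NodeType for n in self.nodes_by_type[t]]

    def n_nodes(self, node_type: NodeType | None = None) -> int:
        if node_type is None:
            return sum(len(v) for v in self.nodes_by_type.values())
        return len(self.nodes_by_type[node_type])

    def edges_of(self, relation: Relation) -> list[TypedEdge]:
        return [e for e in self.edges if e.relation == relation]

    def neighbors(self, node: NodeRef, relation: Relation | None = None) -> list[NodeRef]:
        rels = self.adjacency.get(node, {})
        if relation is not None:
            return list(rels.get(relation, []))
        out: list[NodeRef] = []
        for lst in rels.values():
            out.extend(lst)
        return sorted(out)

    def degree(self, node: NodeRef) -> int:
        return len(self.neighbors(node))

    def has_edge(self, a: NodeRef, b: NodeRef, relation: Relation) -> bool:
        return b in self.adjacency.get(a, {}).get(relation, [])


@dataclass
class CandidatePairSet:
    """Cartesian product of query-type nodes x cancers with binary labels."""

    query_type: NodeType
    pairs: list[tuple[NodeRef, NodeRef, int]] = field(default_factory=list)

    @property
    def queries(self) -> list[NodeRef]:
        seen: dict[NodeRef, None] = {}
        for q, _, _ in self.pairs:
            seen.setdefault(q)
        return list(seen)

    @property
    def n_positive(self) -> int:
        return sum(lbl for _, _, lbl in self.pairs)

    @property
    def n_negative(self) -> int:
        return len(self.pairs) - self.n_positive


# ---------------------------------------------------------------------------
# I/O and assembly
# ---------------------------------------------------------------------------

def _read_one(path, relation: Relation) -> list[TypedEdge]:
    src_t, tgt_t = RELATION_TYPES[relation]
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ValueError(f"{path}: cannot parse edge list ({exc})") from exc
    if list(df.columns[:2]) != ["source_id", "target_id"]:
        raise ValueError(
            f"{path}: expected header 'source_id\\ttarget_id', got {list(df.columns)}"
        )
    edges: list[TypedEdge] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        s, t = row.source_id, row.target_id
        if not isinstance(s, str) or not isinstance(t, str) or not s or not t:
            raise ValueError(f"{path}:{i}: malformed row {s!r}\t{t!r}")
        if s == t:
            raise ValueError(
                f"{path}:{i}: self loop / type mismatch: {s!r} on both endpoints"
            )
        if (s, t) in seen:
            n_dup += 1
            continue
        seen.add((s, t))
        edges.append(
            TypedEdge(NodeRef(s, src_t), NodeRef(t, tgt_t), relation)
        )
    if n_dup:
        logger.warning("%s: collapsed %d duplicate row(s)", path, n_dup)
    return edges


def read_edge_lists(paths: Mapping[Relation | str, object]) -> list[TypedEdge]:
    """Read per-relation TSV edge lists (header ``source_id<TAB>target_id``).

    ``paths`` maps each relation to its file; the relation of every edge is
    inferred from which file it came from.  Duplicate rows are collapsed
    with a logged warning.
    """
    edges: list[TypedEdge] = []
    for rel, path in paths.items():
        rel = Relation(rel)
        edges.extend(_read_one(path, rel))
    return edges


def build_network(edges: Sequence[TypedEdge]) -> HeteroNetwork:
    """Assemble a :class:`HeteroNetwork`; isolated nodes cannot occur since
    only edge endpoints enter the node set."""
    if not edges:
        raise ValueError("no edges given")
    return HeteroNetwork(edges)


def enumerate_candidate_pairs(
    net: HeteroNetwork, query_type: NodeType | str
) -> CandidatePairSet:
    """All (query, cancer) pairs; label 1 iff the association is observed.

    Unobserved pairs are the negative class, so
    ``n_positive + n_negative == n_query * n_cancer`` exactly.
    """
    query_type = NodeType(query_type)
    if query_type not in (NodeType.CIRCRNA, NodeType.DRUG):
        raise ValueError(f"query_type must be circRNA or drug, got {query_type}")
    relation = (
        Relation.CIRC_CANCER if query_type is NodeType.CIRCRNA else Relation.DRUG_CANCER
    )
    queries = net.nodes_by_type[query_type]
    cancers = net.nodes_by_type[NodeType.CANCER]
    if not queries or not cancers:
        raise ValueError("network lacks query-type nodes or cancers")
    pairs = [
        (q, c, int(net.has_edge(q, c, relation))) for q in queries for c in cancers
    ]
    return CandidatePairSet(query_type=query_type, pairs=pairs)


def network_stats(net: HeteroNetwork) -> dict:
    """Summary record: per-type node counts, per-relation edge counts, totals
    and degree summaries."""
    degs = [net.degree(n) for n in net.nodes]
    return {
        "n_nodes": net.n_nodes(),
        "n_edges": len(net.edges),
        "nodes_per_type": {t.value: net.n_nodes(t) for t in NodeType},
        "edges_per_relation": {r.value: len(net.edges_of(r)) for r in Relation},
        "degree": {
            "min": int(min(degs)),
            "max": int(max(degs)),
            "mean": float(np.mean(degs)),
        },
    }


def write_network_summary(net: HeteroNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_stats(net), fh, indent=2)


def write_edge_list(net: HeteroNetwork, path) -> None:
    """Canonical merged edge list TSV."""
    rows = [
        {
            "source_id": e.source.id,
            "source_type": e.source.node_type.value,
            "target_id": e.target.id,
            "target_type": e.target.node_type.value,
            "relation": e.relation.value,
        }
        for e in net.edges
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# circRNA-drug sensitivity edges (Wilcoxon rank-sum + BH-FDR)
# ---------------------------------------------------------------------------

def _ranksum_pvalue(low: np.ndarray, high: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration for small untied groups (both sizes <= 8), normal
    approximation with tie correction otherwise.
    """
    pooled = np.concatenate([low, high])
    small = len(low) <= 8 and len(high) <= 8
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(low, high, alternative="two-sided", method=method)
    return float(res.pvalue)


def derive_sensitivity_edges(
    expr: pd.DataFrame,
    resp: pd.DataFrame,
    alpha: float = 0.05,
) -> list[TypedEdge]:
    """Derive circRNA-drug edges from expression vs drug-response data.

    ``expr``: circRNA x sample expression; ``resp``: drug x sample response.
    For each (circRNA, drug) pair, samples are split at the median circRNA
    expression into low/high groups, drug responses of the two groups are
    compared by a two-sided Wilcoxon rank-sum test, p-values are
    Benjamini-Hochberg adjusted across all tested pairs, and an edge is
    emitted iff FDR < ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    shared = [s for s in expr.columns if s in set(resp.columns)]
    if not shared:
        raise ValueError("expression and response matrices share no samples")
    expr = expr[shared]
    resp = resp[shared]
    tested: list[tuple[str, str]] = []
    pvals: list[float] = []
    for circ in expr.index:
        e = expr.loc[circ].to_numpy(dtype=float)
        med = np.median(e)
        lo_mask = e <= med
        hi_mask = ~lo_mask
        for drug in resp.index:
            r = resp.loc[drug].to_numpy(dtype=float)
            lo, hi = r[lo_mask], r[hi_mask]
            if len(lo) < 2 or len(hi) < 2:
                logger.warning(
                    "pair (%s, %s): fewer than 2 samples per group, skipped",
                    circ,
                    drug,
                )
                continue
            tested.append((str(circ), str(drug)))
            pvals.append(_ranksum_pvalue(lo, hi))
    if not tested:
        return []
    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return [
        TypedEdge(
            NodeRef(circ, NodeType.CIRCRNA), NodeRef(drug, NodeType.DRUG),
            Relation.CIRC_DRUG,
        )
        for (circ, drug), q in zip(tested, qvals)
        if q < alpha
    ]
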