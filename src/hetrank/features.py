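"""Node attribute features from interaction profiles.

Each node type gets a square similarity matrix computed with the Gaussian
interaction profile (GIP) kernel over its binary interaction profiles,
optionally fused element-wise with an externally supplied similarity source
(disease semantic, circRNA functional or drug chemical-structure similarity,
all accepted as precomputed matrices).  A node's attribute feature vector is
its row of the fused similarity matrix of its own type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hetnet import HeteroNetwork, NodeRef, NodeType, Relation, RELATION_TYPES


@dataclass
class InteractionProfileMatrix:
    """Binary |A| x |B| matrix; entry 1 iff the corresponding edge exists."""

    rows: list[NodeRef]
    cols: list[NodeRef]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        assert self.values.shape == (len(self.rows), len(self.cols))
        assert set(np.unique(self.values)) <= {0.0, 1.0}


@dataclass
class SimilarityMatrix:
    """Symmetric similarity matrix with unit diagonal over an ordered node list."""

    nodes: list[NodeRef]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.nodes)
        assert self.values.shape == (n, n)

    def row(self, node: NodeRef) -> np.ndarray:
        return self.values[self.nodes.index(node)]

    def to_frame(self) -> pd.DataFrame:
        ids = [n.id for n in self.nodes]
        return pd.DataFrame(self.values, index=ids, columns=ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def read_similarity_tsv(path, node_type: NodeType) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    nodes = [NodeRef(str(i), node_type) for i in df.index]
    return SimilarityMatrix(nodes=nodes, values=df.to_numpy(dtype=float))


def _relation_between(a: NodeType, b: NodeType) -> Relation:
    for rel, (s, t) in RELATION_TYPES.items():
        if {s, t} == {a, b}:
            return rel
    raise ValueError(f"no relation connects {a.value} and {b.value}")


def interaction_profile(
    net: HeteroNetwork,
    row_type: NodeType | str,
    col_type: NodeType | str,
    universe: HeteroNetwork | None = None,
) -> InteractionProfileMatrix:
    """Binary interaction profile of ``row_type`` nodes against ``col_type``.

    Edges come from ``net``; the node lists come from ``universe`` when
    given (so nodes whose edges are all masked out keep an all-zero row
    instead of disappearing).
    """
    row_type, col_type = NodeType(row_type), NodeType(col_type)
    rel = _relation_between(row_type, col_type)
    src = universe if universe is not None else net
    rows = src.nodes_by_type[row_type]
    cols = src.nodes_by_type[col_type]
    col_index = {c: j for j, c in enumerate(cols)}
    m = np.zeros((len(rows), len(cols)))
    for i, r in enumerate(rows):
        for nbr in net.neighbors(r, rel):
            m[i, col_index[nbr]] = 1.0
    return InteractionProfileMatrix(rows=rows, cols=cols, values=m)


def gip_kernel(
    profiles: InteractionProfileMatrix, axis: str = "rows"
) -> SimilarityMatrix:
    """Gaussian interaction profile kernel similarity.

    K(i, j) = exp(-gamma * ||IP(i) - IP(j)||^2) with the bandwidth
    normalised by the mean squared profile norm,
    gamma = 1 / mean_i ||IP(i)||^2 (gamma = 1 if all profiles are zero).
    """
    if axis not in ("rows", "cols"):
        raise ValueError("axis must be 'rows' or 'cols'")
    ip = profiles.values if axis == "rows" else profiles.values.T
    nodes = profiles.rows if axis == "rows" else profiles.cols
    if ip.size == 0:
        raise ValueError("empty profile matrix")
    sq_norms = (ip**2).sum(axis=1)
    mean_sq = float(sq_norms.mean())
    gamma = 1.0 / mean_sq if mean_sq > 0 else 1.0
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * ip @ ip.T
    np.maximum(d2, 0.0, out=d2)
    k = np.exp(-gamma * d2)
    k = (k + k.T) / 2.0
    np.fill_diagonal(k, 1.0)
    return SimilarityMatrix(nodes=list(nodes), values=k)


def fuse_similarity(
    gip: SimilarityMatrix, other: SimilarityMatrix | None = None
) -> SimilarityMatrix:
    """Fuse GIP similarity with an external similarity source.

    Element-wise mean where ``other`` has a defined (non-NaN) entry, the GIP
    value elsewhere; GIP alone when ``other`` is absent.
    """
    if other is None:
        return SimilarityMatrix(nodes=list(gip.nodes), values=gip.values.copy())
    if other.nodes != gip.nodes:
        raise ValueError("similarity matrices must share node ordering")
    fused = gip.values.copy()
    defined = ~np.isnan(other.values)
    fused[defined] = (gip.values[defined] + other.values[defined]) / 2.0
    fused = (fused + fused.T) / 2.0
    np.fill_diagonal(fused, 1.0)
    return SimilarityMatrix(nodes=list(gip.nodes), values=fused)


#: which relation supplies each node type's interaction profile, per task.
#: cancers profile against the query type of the task at hand.
PROFILE_RELATION = {
    NodeType.CIRCRNA: (NodeType.CIRCRNA, NodeType.CANCER),
    NodeType.DRUG: (NodeType.DRUG, NodeType.CANCER),
}


def node_attribute_features(
    net: HeteroNetwork,
    query_type: NodeType | str = NodeType.CIRCRNA,
    external: dict[NodeType, SimilarityMatrix] | None = None,
    concat_profiles: bool = False,
    universe: HeteroNetwork | None = None,
) -> dict[NodeType, np.ndarray]:
    """Per-type attribute feature tables.

    Each node's feature vector is its row of its type's fused similarity
    matrix (length = number of nodes of that type, unit entry at its own
    position).  Cancer profiles are taken against the task's query type;
    with ``concat_profiles`` every type's profile concatenates all relations
    the type participates in before the kernel.
    """
    query_type = NodeType(query_type)
    external = external or {}
    src = universe if universe is not None else net
    out: dict[NodeType, np.ndarray] = {}
    for t in NodeType:
        if not src.nodes_by_type[t]:
            continue
        if concat_profiles:
            blocks = []
            for other in NodeType:
                if other is t:
                    continue
                try:
                    blocks.append(
                        interaction_profile(net, t, other, universe=universe).values
                    )
                except ValueError:
                    continue
            prof = InteractionProfileMatrix(
                rows=src.nodes_by_type[t],
                cols=[
                    NodeRef(f"col{j}", t) for j in range(sum(b.shape[1] for b in blocks))
                ],
                values=np.concatenate(blocks, axis=1),
            )
        elif t is NodeType.CANCER:
            prof = interaction_profile(net, NodeType.CANCER, query_type, universe=universe)
        else:
            prof = interaction_profile(net, *PROFILE_RELATION[t], universe=universe)
        sim = fuse_similarity(gip_kernel(prof), external.get(t))
        out[t] = sim.values
    return out
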