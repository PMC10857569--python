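"""Edge-embedding GNN with differentiable architecture search.

A two-phase model over the heterogeneous network:

* message passing — per layer, an intra-layer cell aggregates neighbour
  messages (sum / max / mean), combines them with the node's own
  transformed state (sum / concat) and applies an activation
  (ReLU / PReLU); an inter-layer component connects consecutive layers
  (stack / skip_sum / skip_concat) and aggregates layer outputs
  (last / concat / max / none);
* readout — an edge embedding ``H_e`` for a candidate (query, cancer)
  pair is pooled from the two endpoint node states (sum / max / concat,
  query first for concat).

Every operation named above is a search decision.  The search relaxes the
discrete choices with Gumbel-softmax samples (temperature-annealed), trains
the relaxed mixture jointly with the model weights on a link-prediction
binary cross-entropy, then fixes each decision by argmax and retrains the
weights from scratch under the discrete architecture.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .hetnet import CandidatePairSet, HeteroNetwork, NodeRef, NodeType, Relation

logger = logging.getLogger("hetrank")

AGG_CHOICES = ("sum", "max", "mean")
COMBINE_CHOICES = ("sum", "concat")
ACT_CHOICES = ("relu", "prelu")
CONNECT_CHOICES = ("stack", "skip_sum", "skip_concat")
LAYER_AGG_CHOICES = ("last", "concat", "max", "none")
POOL_CHOICES = ("sum", "max", "concat")

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class SearchSpace:
    """Candidate sets for every architecture decision."""

    agg: tuple[str, ...] = AGG_CHOICES
    combine: tuple[str, ...] = COMBINE_CHOICES
    activation: tuple[str, ...] = ACT_CHOICES
    connect: tuple[str, ...] = CONNECT_CHOICES
    layer_agg: tuple[str, ...] = LAYER_AGG_CHOICES
    pool: tuple[str, ...] = POOL_CHOICES
    n_layers: int = 2

    def __post_init__(self) -> None:
        for name, cands, allowed in [
            ("agg", self.agg, AGG_CHOICES),
            ("combine", self.combine, COMBINE_CHOICES),
            ("activation", self.activation, ACT_CHOICES),
            ("connect", self.connect, CONNECT_CHOICES),
            ("layer_agg", self.layer_agg, LAYER_AGG_CHOICES),
            ("pool", self.pool, POOL_CHOICES),
        ]:
            if not cands or not set(cands) <= set(allowed):
                raise ValueError(f"invalid candidates for {name}: {cands}")

    def decisions(self) -> list[tuple[str, tuple[str, ...]]]:
        """Flat list of (decision name, candidates), per-layer first."""
        out: list[tuple[str, tuple[str, ...]]] = []
        for k in range(self.n_layers):
            out += [
                (f"agg_{k}", self.agg),
                (f"combine_{k}", self.combine),
                (f"activation_{k}", self.activation),
                (f"connect_{k}", self.connect),
            ]
        out += [("layer_agg", self.layer_agg), ("pool", self.pool)]
        return out


@dataclass
class Architecture:
    """One concrete operation choice per search decision."""

    agg: list[str]
    combine: list[str]
    activation: list[str]
    connect: list[str]
    layer_agg: str
    pool: str

    @property
    def n_layers(self) -> int:
        return len(self.agg)

    def validate(self, space: SearchSpace) -> None:
        assert len(self.agg) == space.n_layers
        for k in range(space.n_layers):
            assert self.agg[k] in space.agg
            assert self.combine[k] in space.combine
            assert self.activation[k] in space.activation
            assert self.connect[k] in space.connect
        assert self.layer_agg in space.layer_agg
        assert self.pool in space.pool

    def to_table(self) -> dict[str, str]:
        """Human-readable summary, one row per operation family."""
        cap = lambda s: s.capitalize()
        return {
            "Agg": ", ".join(cap(a) for a in self.agg),
            "Combine": ", ".join(cap(c) for c in self.combine),
            "Activation": ", ".join(
                {"relu": "Relu", "prelu": "Prelu"}[a] for a in self.activation
            ),
            "Layer Connect": ", ".join(cap(c) for c in self.connect),
            "Layer Aggregation": cap(self.layer_agg),
            "Pool": cap(self.pool),
        }


@dataclass
class ArchitectureParams:
    """Relaxed architecture distribution: log-weights per candidate."""

    log_weights: dict[str, np.ndarray]
    tau: float = 1.0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("temperature tau must be positive")
        for name, lw in self.log_weights.items():
            if not np.all(np.isfinite(lw)):
                raise ValueError(f"non-finite log-weight for decision {name}")


def gumbel_softmax_sample(
    weights: np.ndarray, u: np.ndarray, tau: float
) -> np.ndarray:
    """Relaxed one-hot sample over candidate operations.

    eps_o = exp((log w_o - log(-log U_o)) / tau) / sum_o' exp(...), with
    U_o ~ Uniform(0,1).  As tau -> 0 the sample approaches the one-hot
    indicator of argmax_o (log w_o - log(-log U_o)).
    """
    weights = np.asarray(weights, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("operation weights must be positive (store log-weights)")
    if not tau > 0:
        raise ValueError("tau must be positive")
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("uniform draws must lie in (0, 1)")
    z = (np.log(weights) - np.log(-np.log(u))) / tau
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


@dataclass
class GnnConfig:
    hidden_dim: int = 64
    n_layers: int = 2
    search_epochs: int = 150
    train_epochs: int = 200
    learning_rate: float = 0.01
    tau_start: float = 1.0
    tau_end: float = 0.1
    #: per-epoch probability of hiding an adjacency entry during training
    #: (DropEdge-style regularisation against memorising observed links)
    edge_dropout: float = 0.25
    seed: int = 0


# ---------------------------------------------------------------------------
# graph preparation
# ---------------------------------------------------------------------------

@dataclass
class GraphData:
    """Node ordering, undirected adjacency and per-type input features."""

    nodes: list[NodeRef]
    index: dict[NodeRef, int]
    adj: list[np.ndarray]
    feat: dict[NodeType, np.ndarray]

    @classmethod
    def from_network(
        cls,
        net: HeteroNetwork,
        features: dict[NodeType, np.ndarray],
        universe: HeteroNetwork | None = None,
    ) -> "GraphData":
        """Adjacency from ``net``; node set from ``universe`` when given, so
        nodes whose edges are all masked keep a (degree-0) slot."""
        src = universe if universe is not None else net
        nodes = [n for t in NodeType for n in src.nodes_by_type[t]]
        index = {n: i for i, n in enumerate(nodes)}
        adj: list[np.ndarray] = [
            np.array(
                [index[u] for u in net.neighbors(n)], dtype=np.intp
            )
            for n in nodes
        ]
        return cls(nodes=nodes, index=index, adj=adj, feat=features)


# ---------------------------------------------------------------------------
# forward building blocks (autodiff tensors; public ops wrap these)
# ---------------------------------------------------------------------------

def _activate(x: Tensor, kind: str, slope: Tensor) -> Tensor:
    if kind == "relu":
        return T.relu(x)
    if kind == "prelu":
        return T.prelu(x, slope)
    raise ValueError(f"unknown activation {kind!r}")


def _mpnn_layer_t(
    h: Tensor,
    adj: list[np.ndarray],
    agg: str,
    combine: str,
    activation: str,
    w_self: Tensor,
    w_neigh: Tensor,
    w_comb: Tensor,
    slope: Tensor,
) -> Tensor:
    """One intra-layer cell: aggregate, combine, activate."""
    msgs = T.matmul(h, w_neigh)
    x = T.neighbor_agg(msgs, adj, agg)
    own = T.matmul(h, w_self)
    if combine == "sum":
        comb = T.add(own, x)
    elif combine == "concat":
        comb = T.matmul(T.concat([own, x], axis=1), w_comb)
    else:
        raise ValueError(f"unknown combine {combine!r}")
    return _activate(comb, activation, slope)


def _layer_connect_t(
    h_prev: Tensor, h_k: Tensor, choice: str, w_con: Tensor | None
) -> Tensor:
    if choice == "stack":
        return h_k
    if choice == "skip_sum":
        if h_prev.shape != h_k.shape:
            raise ValueError(
                f"skip_sum width mismatch: {h_prev.shape} vs {h_k.shape}"
            )
        return T.add(h_prev, h_k)
    if choice == "skip_concat":
        assert w_con is not None
        return T.matmul(T.concat([h_prev, h_k], axis=1), w_con)
    raise ValueError(f"unknown layer connection {choice!r}")


def _layer_aggregate_t(hs: list[Tensor], choice: str) -> Tensor:
    if choice in ("last", "none"):
        return hs[-1]
    if choice == "concat":
        return T.concat(hs, axis=1) if len(hs) > 1 else hs[-1]
    if choice == "max":
        out = hs[0]
        for h in hs[1:]:
            out = T.maximum(out, h)
        return out
    raise ValueError(f"unknown layer aggregation {choice!r}")


def _edge_readout_t(h: Tensor, qi: np.ndarray, ci: np.ndarray, pool: str) -> Tensor:
    hq = T.rows(h, qi)
    hc = T.rows(h, ci)
    if pool == "sum":
        return T.add(hq, hc)
    if pool == "max":
        return T.maximum(hq, hc)
    if pool == "concat":
        return T.concat([hq, hc], axis=1)
    raise ValueError(f"unknown pool {pool!r}")


# public numpy-level ops (same code path, gradients off) ---------------------

def init_node_states(
    features: dict[NodeType, np.ndarray],
    projections: dict[NodeType, np.ndarray],
) -> np.ndarray:
    """Project per-type attribute features to a common hidden width and
    stack them in type order.  Linear, no bias: a zero feature vector maps
    to a zero state."""
    blocks = [
        features[t] @ projections[t] for t in NodeType if t in features
    ]
    return np.concatenate(blocks, axis=0)


def mpnn_layer(
    h: np.ndarray,
    adj: list[np.ndarray],
    agg: str,
    combine: str,
    activation: str,
    w_self: np.ndarray,
    w_neigh: np.ndarray,
    w_comb: np.ndarray | None = None,
    prelu_slope: float = 0.25,
) -> np.ndarray:
    if combine == "concat" and w_comb is None:
        d = w_self.shape[1]
        w_comb = np.concatenate([np.eye(d), np.eye(d)], axis=0)
    out = _mpnn_layer_t(
        Tensor(h), adj, agg, combine, activation,
        Tensor(w_self), Tensor(w_neigh),
        Tensor(w_comb if w_comb is not None else np.zeros((0, 0))),
        Tensor(np.array([prelu_slope])),
    )
    return out.data


def layer_connect(
    h_prev: np.ndarray, h_k: np.ndarray, choice: str, w: np.ndarray | None = None
) -> np.ndarray:
    return _layer_connect_t(
        Tensor(h_prev), Tensor(h_k), choice, Tensor(w) if w is not None else None
    ).data


def layer_aggregate(hs: list[np.ndarray], choice: str) -> np.ndarray:
    return _layer_aggregate_t([Tensor(h) for h in hs], choice).data


def edge_readout(
    h: np.ndarray, query_idx: int, cancer_idx: int, pool: str
) -> np.ndarray:
    return _edge_readout_t(
        Tensor(h), np.array([query_idx]), np.array([cancer_idx]), pool
    ).data[0]


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

def _init_weights(
    graph: GraphData, cfg: GnnConfig, rng: np.random.Generator
) -> dict[str, Tensor]:
    """Glorot-style init for every map any candidate may use (so relaxed and
    discrete paths consume the init stream identically)."""
    d = cfg.hidden_dim

    def glorot(shape):
        lim = np.sqrt(6.0 / sum(shape))
        return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)

    w: dict[str, Tensor] = {}
    for t in NodeType:
        if t in graph.feat:
            w[f"in_{t.value}"] = glorot((graph.feat[t].shape[1], d))
    for k in range(cfg.n_layers):
        w[f"self_{k}"] = glorot((d, d))
        w[f"neigh_{k}"] = glorot((d, d))
        w[f"comb_{k}"] = glorot((2 * d, d))
        w[f"con_{k}"] = glorot((2 * d, d))
        w[f"slope_{k}"] = Tensor(np.array([0.25]), requires_grad=True)
    # mixing projections used only while the search is relaxed
    w["lagg_mix"] = glorot((cfg.n_layers * d, d))
    w["pool_mix"] = glorot((2 * d, d))
    return w


def _head_for(weights: dict[str, Tensor], dim: int, rng: np.random.Generator) -> Tensor:
    key = f"head_{dim}"
    if key not in weights:
        lim = np.sqrt(6.0 / (dim + 1))
        weights[key] = Tensor(rng.uniform(-lim, lim, size=(dim, 1)), requires_grad=True)
    return weights[key]


def _input_states(graph: GraphData, weights: dict[str, Tensor]) -> Tensor:
    blocks = [
        T.matmul(Tensor(graph.feat[t]), weights[f"in_{t.value}"])
        for t in NodeType
        if t in graph.feat
    ]
    return T.concat(blocks, axis=0) if len(blocks) > 1 else blocks[0]


def _forward_discrete(
    graph: GraphData, weights: dict[str, Tensor], arch: Architecture
) -> Tensor:
    h = _input_states(graph, weights)
    outs: list[Tensor] = []
    for k in range(arch.n_layers):
        h_new = _mpnn_layer_t(
            h, graph.adj, arch.agg[k], arch.combine[k], arch.activation[k],
            weights[f"self_{k}"], weights[f"neigh_{k}"], weights[f"comb_{k}"],
            weights[f"slope_{k}"],
        )
        h = _layer_connect_t(h, h_new, arch.connect[k], weights[f"con_{k}"])
        outs.append(h)
    return _layer_aggregate_t(outs, arch.layer_agg)


def _forward_relaxed(
    graph: GraphData,
    weights: dict[str, Tensor],
    space: SearchSpace,
    eps: dict[str, Tensor],
) -> Tensor:
    """Soft-mixture forward: every decision's output is the eps-weighted sum
    of its candidate branches.  Width-changing branches (concat layer
    aggregation / concat pooling) are projected to the common width by
    dedicated mixing maps so branches are summable."""
    h = _input_states(graph, weights)
    outs: list[Tensor] = []
    for k in range(space.n_layers):
        msgs = T.matmul(h, weights[f"neigh_{k}"])
        own = T.matmul(h, weights[f"self_{k}"])
        x = T.weighted_sum(
            [T.neighbor_agg(msgs, graph.adj, a) for a in space.agg],
            eps[f"agg_{k}"],
        )
        comb_branches = []
        for c in space.combine:
            if c == "sum":
                comb_branches.append(T.add(own, x))
            else:
                comb_branches.append(
                    T.matmul(T.concat([own, x], axis=1), weights[f"comb_{k}"])
                )
        comb = T.weighted_sum(comb_branches, eps[f"combine_{k}"])
        act = T.weighted_sum(
            [_activate(comb, a, weights[f"slope_{k}"]) for a in space.activation],
            eps[f"activation_{k}"],
        )
        con_branches = []
        for c in space.connect:
            if c == "skip_concat":
                con_branches.append(
                    T.matmul(T.concat([h, act], axis=1), weights[f"con_{k}"])
                )
            else:
                con_branches.append(_layer_connect_t(h, act, c, None))
        h = T.weighted_sum(con_branches, eps[f"connect_{k}"])
        outs.append(h)
    lagg_branches = []
    for c in space.layer_agg:
        if c == "concat" and len(outs) > 1:
            lagg_branches.append(
                T.matmul(T.concat(outs, axis=1), weights["lagg_mix"])
            )
        else:
            lagg_branches.append(_layer_aggregate_t(outs, c if c != "concat" else "last"))
    return T.weighted_sum(lagg_branches, eps["layer_agg"])


def _readout_relaxed(
    h: Tensor, qi, ci, space: SearchSpace, eps: dict[str, Tensor],
    weights: dict[str, Tensor],
) -> Tensor:
    branches = []
    for p in space.pool:
        if p == "concat":
            branches.append(
                T.matmul(_edge_readout_t(h, qi, ci, "concat"), weights["pool_mix"])
            )
        else:
            branches.append(_edge_readout_t(h, qi, ci, p))
    return T.weighted_sum(branches, eps["pool"])


def _bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    # mean(softplus(s) - y*s), the numerically stable binary cross-entropy
    return T.mean_all(T.sub(T.softplus(logits), T.cmul(logits, labels[:, None])))


# ---------------------------------------------------------------------------
# training / search
# ---------------------------------------------------------------------------

def _task_edges(
    net: HeteroNetwork, graph: GraphData, query_type: NodeType
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Positive (query, cancer) index pairs of the task relation plus the
    full index grids for negative sampling."""
    rel = Relation.CIRC_CANCER if query_type is NodeType.CIRCRNA else Relation.DRUG_CANCER
    q_nodes = net.nodes_by_type[query_type]
    c_nodes = net.nodes_by_type[NodeType.CANCER]
    pos = np.array(
        [
            (graph.index[e.source], graph.index[e.target])
            for e in net.edges_of(rel)
        ],
        dtype=np.intp,
    ).reshape(-1, 2)
    qs = np.array([graph.index[q] for q in q_nodes], dtype=np.intp)
    cs = np.array([graph.index[c] for c in c_nodes], dtype=np.intp)
    pos_set = np.zeros((len(graph.nodes), len(graph.nodes)), dtype=bool)
    if len(pos):
        pos_set[pos[:, 0], pos[:, 1]] = True
    neg_q, neg_c = np.meshgrid(qs, cs, indexing="ij")
    mask = ~pos_set[neg_q, neg_c]
    negs = np.stack([neg_q[mask], neg_c[mask]], axis=1)
    return pos, negs, qs, cs


def _epoch_batch(
    pos: np.ndarray, negs: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All positives plus an equal-size uniform sample of unobserved pairs."""
    k = min(len(pos), len(negs))
    sel = rng.choice(len(negs), size=k, replace=False) if len(negs) else np.array([], dtype=int)
    batch = np.concatenate([pos, negs[sel]], axis=0)
    labels = np.concatenate([np.ones(len(pos)), np.zeros(k)])
    return batch[:, 0], batch[:, 1], labels


def _dropped_adj(
    full_adj: list[np.ndarray], p: float, rng: np.random.Generator
) -> list[np.ndarray]:
    if p <= 0:
        return full_adj
    return [nb[rng.random(len(nb)) >= p] for nb in full_adj]


def train_discrete(
    net: HeteroNetwork,
    features: dict[NodeType, np.ndarray],
    arch: Architecture,
    cfg: GnnConfig,
    query_type: NodeType = NodeType.CIRCRNA,
    weights: dict[str, Tensor] | None = None,
    record_loss: bool = False,
    universe: HeteroNetwork | None = None,
) -> tuple["GnnModel", list[float]]:
    """Train model weights under a fixed architecture (link-prediction BCE
    against uniformly sampled unobserved pairs, 1:1 per epoch)."""
    ss = np.random.SeedSequence(cfg.seed)
    init_rng, _gumbel_rng, neg_rng, drop_rng = [
        np.random.default_rng(c) for c in ss.spawn(4)
    ]
    graph = GraphData.from_network(net, features, universe=universe)
    if weights is None:
        weights = _init_weights(graph, cfg, init_rng)
    pos, negs, _, _ = _task_edges(net, graph, query_type)
    if len(pos) == 0:
        raise ValueError("training edge set is empty")
    params = [w for w in weights.values() if w.requires_grad]
    opt = T.Adam(params, lr=cfg.learning_rate)
    losses: list[float] = []
    head_rng = np.random.default_rng(ss.spawn(1)[0])
    full_adj = graph.adj
    for _ in range(cfg.train_epochs):
        qi, ci, labels = _epoch_batch(pos, negs, neg_rng)
        graph.adj = _dropped_adj(full_adj, cfg.edge_dropout, drop_rng)
        h = _forward_discrete(graph, weights, arch)
        he = _edge_readout_t(h, qi, ci, arch.pool)
        head = _head_for(weights, he.shape[1], head_rng)
        if head not in opt.params:
            opt = T.Adam(params + [head], lr=cfg.learning_rate)
        logits = T.matmul(he, head)
        loss = _bce_with_logits(logits, labels)
        if not np.isfinite(loss.data):
            raise RuntimeError("training diverged: non-finite loss")
        opt.zero_grad()
        T.backward(loss)
        opt.step()
        if record_loss:
            losses.append(float(loss.data))
    graph.adj = full_adj
    return GnnModel(arch=arch, weights=weights, graph=graph), losses


def search(
    net: HeteroNetwork,
    features: dict[NodeType, np.ndarray],
    space: SearchSpace | None = None,
    cfg: GnnConfig | None = None,
    query_type: NodeType = NodeType.CIRCRNA,
    record_loss: bool = False,
    universe: HeteroNetwork | None = None,
) -> tuple[Architecture, "GnnModel", list[float]]:
    """Jointly optimise architecture log-weights and model weights on the
    relaxed mixture, anneal the temperature, then retrain the argmax
    architecture from scratch.

    Returns (architecture, trained model, relaxed-phase loss trajectory).
    """
    space = space or SearchSpace()
    cfg = cfg or GnnConfig()
    ss = np.random.SeedSequence(cfg.seed)
    init_rng, gumbel_rng, neg_rng, drop_rng = [
        np.random.default_rng(c) for c in ss.spawn(4)
    ]
    graph = GraphData.from_network(net, features, universe=universe)
    weights = _init_weights(graph, cfg, init_rng)
    decisions = space.decisions()
    logits = {
        name: Tensor(np.zeros(len(cands)), requires_grad=True)
        for name, cands in decisions
    }
    pos, negs, _, _ = _task_edges(net, graph, query_type)
    if len(pos) == 0:
        raise ValueError("training edge set is empty")
    params = [w for w in weights.values() if w.requires_grad] + list(logits.values())
    opt = T.Adam(params, lr=cfg.learning_rate)
    head_rng = np.random.default_rng(ss.spawn(1)[0])
    losses: list[float] = []
    full_adj = graph.adj
    n_ep = max(cfg.search_epochs, 1)
    for ep in range(cfg.search_epochs):
        tau = cfg.tau_start + (cfg.tau_end - cfg.tau_start) * ep / max(n_ep - 1, 1)
        graph.adj = _dropped_adj(full_adj, cfg.edge_dropout, drop_rng)
        eps: dict[str, Tensor] = {}
        for name, cands in decisions:
            u = gumbel_rng.uniform(size=len(cands))
            gumbel = -np.log(-np.log(np.clip(u, 1e-12, 1 - 1e-12)))
            eps[name] = T.softmax1d(
                T.cmul(T.add(logits[name], Tensor(gumbel)), 1.0 / tau)
            )
        qi, ci, labels = _epoch_batch(pos, negs, neg_rng)
        h = _forward_relaxed(graph, weights, space, eps)
        he = _readout_relaxed(h, qi, ci, space, eps, weights)
        head = _head_for(weights, he.shape[1], head_rng)
        if head not in opt.params:
            opt = T.Adam(params + [head], lr=cfg.learning_rate)
        loss = _bce_with_logits(T.matmul(he, head), labels)
        if not np.isfinite(loss.data):
            raise RuntimeError("architecture search diverged: non-finite loss")
        opt.zero_grad()
        T.backward(loss)
        opt.step()
        losses.append(float(loss.data))
    choice = {
        name: cands[int(np.argmax(logits[name].data))] for name, cands in decisions
    }
    arch = Architecture(
        agg=[choice[f"agg_{k}"] for k in range(space.n_layers)],
        combine=[choice[f"combine_{k}"] for k in range(space.n_layers)],
        activation=[choice[f"activation_{k}"] for k in range(space.n_layers)],
        connect=[choice[f"connect_{k}"] for k in range(space.n_layers)],
        layer_agg=choice["layer_agg"],
        pool=choice["pool"],
    )
    arch.validate(space)
    graph.adj = full_adj
    retrain_cfg = GnnConfig(**{**asdict(cfg), "seed": cfg.seed + 1})
    model, _ = train_discrete(
        net, features, arch, retrain_cfg, query_type,
        record_loss=False, universe=universe,
    )
    return arch, model, losses


# ---------------------------------------------------------------------------
# trained model + edge embeddings
# ---------------------------------------------------------------------------

@dataclass
class EdgeEmbeddingTable:
    pairs: list[tuple[NodeRef, NodeRef]]
    vectors: np.ndarray

    def vector(self, query: NodeRef, cancer: NodeRef) -> np.ndarray:
        return self.vectors[self.pairs.index((query, cancer))]


@dataclass
class GnnModel:
    arch: Architecture
    weights: dict[str, Tensor]
    graph: GraphData

    def node_embeddings(self) -> np.ndarray:
        return _forward_discrete(self.graph, self.weights, self.arch).data

    def embed_edges(self, pairs: CandidatePairSet | list) -> EdgeEmbeddingTable:
        """Edge embedding H_e for every requested (query, cancer) pair.

        A node unseen at training time (all of its task edges were masked)
        has no state; its endpoint contributes a zero vector.
        """
        plist = pairs.pairs if isinstance(pairs, CandidatePairSet) else pairs
        plist = [(p[0], p[1]) for p in plist]
        h = self.node_embeddings()
        h = np.concatenate([h, np.zeros((1, h.shape[1]))], axis=0)  # row for missing
        miss = h.shape[0] - 1
        qi = np.array([self.graph.index.get(q, miss) for q, _ in plist])
        ci = np.array([self.graph.index.get(c, miss) for _, c in plist])
        n_missing = int((qi == miss).sum() + (ci == miss).sum())
        if n_missing:
            logger.warning("%d pair endpoint(s) unseen in training graph", n_missing)
        vec = _edge_readout_t(Tensor(h), qi, ci, self.arch.pool).data
        return EdgeEmbeddingTable(pairs=plist, vectors=vec)

    # -- checkpointing ---------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "architecture": asdict(self.arch),
            "architecture_table": self.arch.to_table(),
            "weights": {k: v.data.tolist() for k, v in self.weights.items()},
            "nodes": [[n.id, n.node_type.value] for n in self.graph.nodes],
            "adj": [a.tolist() for a in self.graph.adj],
            "feat": {t.value: f.tolist() for t, f in self.graph.feat.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "GnnModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError("unsupported checkpoint format version")
        arch = Architecture(**payload["architecture"])
        weights = {
            k: Tensor(np.array(v), requires_grad=True)
            for k, v in payload["weights"].items()
        }
        nodes = [NodeRef(i, NodeType(t)) for i, t in payload["nodes"]]
        graph = GraphData(
            nodes=nodes,
            index={n: i for i, n in enumerate(nodes)},
            adj=[np.array(a, dtype=np.intp) for a in payload["adj"]],
            feat={NodeType(t): np.array(f) for t, f in payload["feat"].items()},
        )
        return cls(arch=arch, weights=weights, graph=graph)


def embed_edges(model: GnnModel, pairs: CandidatePairSet | list) -> EdgeEmbeddingTable:
    return model.embed_edges(pairs)


def embedding_similarity_matrix(
    table: EdgeEmbeddingTable, pairs: list | None = None
) -> np.ndarray:
    """Pearson correlation between edge embeddings (symmetric, unit diagonal)."""
    vec = table.vectors
    if pairs is not None:
        idx = [table.pairs.index((p[0], p[1])) for p in pairs]
        vec = vec[idx]
    if len(vec) < 2:
        raise ValueError("need at least two pairs")
    sd = vec.std(axis=1)
    bad = np.where(sd == 0)[0]
    if len(bad):
        raise ValueError(f"zero-variance embedding for pair index {bad.tolist()}")
    r = np.corrcoef(vec)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)
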