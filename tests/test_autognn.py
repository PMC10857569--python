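"""Message passing, readout, Gumbel-softmax relaxation and the search."""

import itertools

import numpy as np
import pytest

import hetrank as hr
from hetrank.autognn import (
    Architecture,
    ArchitectureParams,
    EdgeEmbeddingTable,
    GnnConfig,
    GraphData,
    SearchSpace,
    edge_readout,
    embedding_similarity_matrix,
    gumbel_softmax_sample,
    layer_aggregate,
    layer_connect,
    mpnn_layer,
    search,
    train_discrete,
)
from hetrank.hetnet import NodeRef, NodeType, Relation, TypedEdge


# ---------------------------------------------------------------------------
# intra-layer cell vs an explicit-loop oracle
# ---------------------------------------------------------------------------

def mpnn_oracle(h, adj, agg, combine, activation, w_self, w_neigh, w_comb,
                slope=0.25):
    """Straightforward per-node loops; independent of the vectorised path."""
    n, d_in = h.shape
    d = w_self.shape[1]
    out = np.zeros((n, d))
    for v in range(n):
        msgs = [h[u] @ w_neigh for u in adj[v]]
        if not msgs:
            x = np.zeros(d)
        elif agg == "sum":
            x = np.sum(msgs, axis=0)
        elif agg == "mean":
            x = np.mean(msgs, axis=0)
        elif agg == "max":
            x = np.max(msgs, axis=0)
        own = h[v] @ w_self
        if combine == "sum":
            c = own + x
        else:
            c = np.concatenate([own, x]) @ w_comb
        if activation == "relu":
            out[v] = np.maximum(c, 0)
        else:
            out[v] = np.where(c < 0, slope * c, c)
    return out


@pytest.mark.parametrize(
    "agg,combine,activation",
    list(itertools.product(("sum", "max", "mean"), ("sum", "concat"),
                           ("relu", "prelu"))),
)
def test_mpnn_layer_matches_explicit_loop(agg, combine, activation):
    rng = np.random.default_rng(hash((agg, combine, activation)) % 2**31)
    n, d = 20, 5
    h = rng.normal(size=(n, d))
    adj = [
        np.flatnonzero(rng.random(n) < 0.2).astype(np.intp) for _ in range(n)
    ]
    w_self = rng.normal(size=(d, d))
    w_neigh = rng.normal(size=(d, d))
    w_comb = rng.normal(size=(2 * d, d))
    got = mpnn_layer(h, adj, agg, combine, activation, w_self, w_neigh, w_comb)
    want = mpnn_oracle(h, adj, agg, combine, activation, w_self, w_neigh, w_comb)
    np.testing.assert_allclose(got, want, atol=1e-12)


def test_mpnn_path_graph_hand_computed():
    """Path a-b-c with 1-d states (1,2,3), identity maps, sum/sum/relu."""
    h = np.array([[1.0], [2.0], [3.0]])
    adj = [np.array([1]), np.array([0, 2]), np.array([1])]
    eye = np.eye(1)
    out = mpnn_layer(h, adj, "sum", "sum", "relu", eye, eye)
    np.testing.assert_allclose(out, [[3.0], [6.0], [5.0]])


def test_isolated_node_keeps_self_message():
    rng = np.random.default_rng(0)
    h = rng.normal(size=(3, 4))
    adj = [np.array([], dtype=np.intp)] * 3
    w = rng.normal(size=(4, 4))
    out = mpnn_layer(h, adj, "sum", "sum", "relu", w, w)
    np.testing.assert_allclose(out, np.maximum(h @ w, 0))


@pytest.mark.parametrize("agg", ["sum", "max", "mean"])
def test_neighbor_order_irrelevant(agg):
    rng = np.random.default_rng(1)
    h = rng.normal(size=(6, 3))
    w = rng.normal(size=(3, 3))
    adj1 = [np.array([1, 2, 4]), np.array([0])] + [np.array([], dtype=np.intp)] * 4
    adj2 = [np.array([4, 1, 2]), np.array([0])] + [np.array([], dtype=np.intp)] * 4
    a = mpnn_layer(h, adj1, agg, "sum", "relu", w, w)
    b = mpnn_layer(h, adj2, agg, "sum", "relu", w, w)
    np.testing.assert_allclose(a, b)


# ---------------------------------------------------------------------------
# inter-layer operations and readout
# ---------------------------------------------------------------------------

class TestLayerConnect:
    def test_stack_is_identity(self):
        h1, h2 = np.ones((2, 3)), np.full((2, 3), 2.0)
        np.testing.assert_array_equal(layer_connect(h1, h2, "stack"), h2)

    def test_skip_sum(self):
        h1, h2 = np.ones((2, 3)), np.full((2, 3), 2.0)
        np.testing.assert_array_equal(layer_connect(h1, h2, "skip_sum"),
                                      np.full((2, 3), 3.0))

    def test_skip_concat_with_stacked_identities_equals_skip_sum(self):
        rng = np.random.default_rng(2)
        h1, h2 = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        w = np.concatenate([np.eye(3), np.eye(3)], axis=0)
        np.testing.assert_allclose(
            layer_connect(h1, h2, "skip_concat", w),
            layer_connect(h1, h2, "skip_sum"),
        )

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            layer_connect(np.ones((2, 3)), np.ones((2, 4)), "skip_sum")


class TestLayerAggregate:
    def test_single_layer_all_choices_identical(self):
        h = np.random.default_rng(3).normal(size=(4, 2))
        for choice in ("last", "concat", "max", "none"):
            np.testing.assert_array_equal(layer_aggregate([h], choice), h)

    def test_elementwise_max(self):
        a, b = np.array([[1.0, 5.0]]), np.array([[3.0, 2.0]])
        np.testing.assert_array_equal(layer_aggregate([a, b], "max"),
                                      [[3.0, 5.0]])

    def test_concat_width(self):
        hs = [np.ones((3, 4)), np.zeros((3, 4))]
        assert layer_aggregate(hs, "concat").shape == (3, 8)


class TestEdgeReadout:
    def test_sum_pool(self):
        h = np.array([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_array_equal(edge_readout(h, 0, 1, "sum"), [1.0, 1.0])

    def test_sum_and_max_symmetric_concat_ordered(self):
        h = np.random.default_rng(4).normal(size=(3, 4))
        for pool in ("sum", "max"):
            np.testing.assert_allclose(edge_readout(h, 0, 2, pool),
                                       edge_readout(h, 2, 0, pool))
        ab = edge_readout(h, 0, 2, "concat")
        ba = edge_readout(h, 2, 0, "concat")
        assert not np.allclose(ab, ba)
        np.testing.assert_array_equal(ab[:4], h[0])

    def test_max_pool_idempotent(self):
        h = np.random.default_rng(5).normal(size=(2, 6))
        np.testing.assert_array_equal(edge_readout(h, 1, 1, "max"), h[1])


# ---------------------------------------------------------------------------
# Gumbel-softmax
# ---------------------------------------------------------------------------

class TestGumbelSoftmax:
    def test_simplex(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            w = rng.random(4) + 0.1
            u = rng.random(4) * 0.98 + 0.01
            eps = gumbel_softmax_sample(w, u, tau=rng.random() + 0.1)
            assert eps.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(eps >= 0)

    def test_equal_weights_equal_draws_uniform(self):
        eps = gumbel_softmax_sample(np.ones(5), np.full(5, 0.3), tau=1.0)
        np.testing.assert_allclose(eps, 0.2, atol=1e-12)

    def test_low_temperature_approaches_one_hot_argmax(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            w = rng.random(6) + 0.05
            u = rng.random(6) * 0.98 + 0.01
            eps = gumbel_softmax_sample(w, u, tau=1e-4)
            star = int(np.argmax(np.log(w) - np.log(-np.log(u))))
            onehot = np.eye(6)[star]
            np.testing.assert_allclose(eps, onehot, atol=1e-6)

    def test_sampling_distribution_matches_softmax(self):
        """The probability that candidate o dominates a draw equals
        softmax(log w)_o (Gumbel-max trick); the mean of the relaxed
        samples tracks it within Monte-Carlo error."""
        rng = np.random.default_rng(8)
        w = np.array([0.2, 1.0, 3.0])
        draws = np.stack(
            [gumbel_softmax_sample(w, rng.random(3), 1.0) for _ in range(4000)]
        )
        target = w / w.sum()
        argmax_freq = np.bincount(draws.argmax(axis=1), minlength=3) / len(draws)
        np.testing.assert_allclose(argmax_freq, target, atol=0.03)
        # the relaxed mean is smoothed toward uniform but keeps the ordering
        assert list(np.argsort(draws.mean(axis=0))) == list(np.argsort(target))
        np.testing.assert_allclose(draws.mean(axis=0), target, atol=0.12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            gumbel_softmax_sample(np.array([0.0, 1.0]), np.array([0.5, 0.5]), 1.0)
        with pytest.raises(ValueError):
            gumbel_softmax_sample(np.ones(2), np.array([0.0, 0.5]), 1.0)
        with pytest.raises(ValueError):
            gumbel_softmax_sample(np.ones(2), np.full(2, 0.5), 0.0)
        with pytest.raises(ValueError):
            ArchitectureParams(log_weights={"a": np.array([np.inf])})


# ---------------------------------------------------------------------------
# search and training
# ---------------------------------------------------------------------------

def _toy_features(net, rng):
    return {
        t: rng.normal(size=(net.n_nodes(t), 4))
        for t in NodeType
        if net.n_nodes(t)
    }


def test_degenerate_search_space_equals_plain_training(desk_net):
    """With one candidate per decision the relaxed mixture is the discrete
    network, so the loss trajectories coincide exactly."""
    net, _ = desk_net
    feats = hr.node_attribute_features(net, "circRNA")
    space = SearchSpace(
        agg=("sum",), combine=("sum",), activation=("relu",),
        connect=("stack",), layer_agg=("last",), pool=("sum",),
    )
    cfg = GnnConfig(search_epochs=15, train_epochs=15, seed=5)
    arch, _, search_losses = search(net, feats, space, cfg)
    arch2 = Architecture(agg=["sum", "sum"], combine=["sum", "sum"],
                         activation=["relu", "relu"], connect=["stack", "stack"],
                         layer_agg="last", pool="sum")
    _, train_losses = train_discrete(net, feats, arch2, cfg, record_loss=True)
    np.testing.assert_allclose(search_losses, train_losses, rtol=1e-10)


def test_search_returns_valid_architecture(desk_net):
    net, _ = desk_net
    feats = hr.node_attribute_features(net, "circRNA")
    cfg = GnnConfig(search_epochs=20, train_epochs=20, seed=2)
    arch, model, _ = search(net, feats, cfg=cfg)
    arch.validate(SearchSpace())
    table = arch.to_table()
    assert set(table) == {"Agg", "Combine", "Activation", "Layer Connect",
                          "Layer Aggregation", "Pool"}


def _max_separable_network(rng):
    """Association with one cancer is signalled by a single marker-drug
    neighbour among a variable number of filler drugs: max aggregation
    detects the marker, sum accumulates degree noise, mean dilutes it."""
    marker = NodeRef("drug_marker", NodeType.DRUG)
    fillers = [NodeRef(f"drug_f{i}", NodeType.DRUG) for i in range(10)]
    cancer = NodeRef("cancer_0", NodeType.CANCER)
    edges = [TypedEdge(marker, cancer, Relation.DRUG_CANCER)]
    queries = []
    for i in range(30):
        q = NodeRef(f"circ_{i:02d}", NodeType.CIRCRNA)
        queries.append(q)
        positive = i < 15
        n_fill = int(rng.integers(3, 10))
        for f in rng.choice(10, size=n_fill, replace=False):
            edges.append(TypedEdge(q, fillers[f], Relation.CIRC_DRUG))
        if positive:
            edges.append(TypedEdge(q, marker, Relation.CIRC_DRUG))
            edges.append(TypedEdge(q, cancer, Relation.CIRC_CANCER))
    net = hr.build_network(edges)
    feats = {}
    drugs = net.nodes_by_type[NodeType.DRUG]
    feats[NodeType.DRUG] = np.array(
        [[1.0] if d.id == "drug_marker" else [0.1] for d in drugs]
    )
    feats[NodeType.CIRCRNA] = np.zeros((net.n_nodes(NodeType.CIRCRNA), 1))
    feats[NodeType.CANCER] = np.zeros((net.n_nodes(NodeType.CANCER), 1))
    return net, feats


def test_search_prefers_max_aggregation_when_only_max_separates():
    rng = np.random.default_rng(0)
    hits = 0
    for seed in range(10):
        net, feats = _max_separable_network(np.random.default_rng(100 + seed))
        cfg = GnnConfig(hidden_dim=8, search_epochs=60, train_epochs=5,
                        seed=seed, edge_dropout=0.0)
        arch, _, _ = search(net, feats, cfg=cfg)
        hits += arch.agg[0] == "max"
    assert hits / 10 > 1 / 3  # better than uniform choice over {sum,max,mean}


def test_training_separates_observed_from_unobserved_pairs(desk_net):
    """Median training AUC across 3 seeds on the synthetic network."""
    net, _ = desk_net
    feats = hr.node_attribute_features(net, "circRNA")
    arch = Architecture(agg=["max", "max"], combine=["concat", "concat"],
                        activation=["prelu", "relu"],
                        connect=["skip_sum", "stack"],
                        layer_agg="concat", pool="max")
    pairs = hr.enumerate_candidate_pairs(net, "circRNA")
    labels = np.array([l for _, _, l in pairs.pairs])
    aucs = []
    for seed in (0, 1, 2):
        cfg = GnnConfig(train_epochs=200, seed=seed, edge_dropout=0.0)
        model, _ = train_discrete(net, feats, arch, cfg)
        table = model.embed_edges(pairs)
        head = model.weights[
            [k for k in model.weights if k.startswith("head")][0]
        ].data
        scores = (table.vectors @ head).ravel()
        aucs.append(hr.auc(labels, scores))
    assert np.median(aucs) >= 0.95


# ---------------------------------------------------------------------------
# edge embeddings
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def trained_model():
    net, _ = hr.generate_hetnet(hr.desk_config(seed=11))
    feats = hr.node_attribute_features(net, "circRNA")
    arch = Architecture(agg=["max", "max"], combine=["concat", "concat"],
                        activation=["prelu", "relu"],
                        connect=["skip_sum", "stack"],
                        layer_agg="concat", pool="max")
    model, _ = train_discrete(net, feats, arch, GnnConfig(train_epochs=60, seed=3))
    return net, model


class TestEmbedEdges:
    def test_deterministic(self, trained_model):
        net, model = trained_model
        pairs = hr.enumerate_candidate_pairs(net, "circRNA")
        t1 = model.embed_edges(pairs)
        t2 = model.embed_edges(pairs)
        np.testing.assert_array_equal(t1.vectors, t2.vectors)

    def test_dimension_follows_pool_and_layer_aggregation(self, desk_net):
        net, _ = desk_net
        feats = hr.node_attribute_features(net, "circRNA")
        pairs = hr.enumerate_candidate_pairs(net, "circRNA")
        d = 16
        for pool, lagg, factor in (("sum", "last", 1), ("concat", "last", 2),
                                   ("max", "concat", 2), ("concat", "concat", 4)):
            arch = Architecture(agg=["sum", "sum"], combine=["sum", "sum"],
                                activation=["relu", "relu"],
                                connect=["stack", "stack"],
                                layer_agg=lagg, pool=pool)
            model, _ = train_discrete(
                net, feats, arch, GnnConfig(hidden_dim=d, train_epochs=2, seed=0)
            )
            table = model.embed_edges(pairs.pairs[:5])
            assert table.vectors.shape == (5, factor * d)

    def test_relabeling_nodes_preserves_embeddings(self, desk_net):
        """Renaming node ids permutes internal order but leaves each pair's
        embedding unchanged for permutation-invariant aggregation/pooling."""
        net, _ = desk_net
        rng = np.random.default_rng(9)
        feats_by_node = {
            n: rng.normal(size=4) for n in net.nodes
        }
        arch = Architecture(agg=["sum", "sum"], combine=["sum", "sum"],
                            activation=["relu", "relu"],
                            connect=["stack", "stack"],
                            layer_agg="last", pool="sum")

        def orig_id(s):  # inverse of the rename below
            return s[2:][::-1]

        edges2 = [
            TypedEdge(
                NodeRef("zz" + e.source.id[::-1], e.source.node_type),
                NodeRef("zz" + e.target.id[::-1], e.target.node_type),
                e.relation,
            )
            for e in net.edges
        ]
        net1, net2 = net, hr.build_network(edges2)
        f1 = {
            t: np.stack([feats_by_node[n] for n in net1.nodes_by_type[t]])
            for t in NodeType
        }
        cfg = GnnConfig(hidden_dim=8, train_epochs=4, seed=1, edge_dropout=0.0)
        m1, _ = train_discrete(net1, f1, arch, cfg)
        f2 = {
            t: np.stack(
                [feats_by_node[NodeRef(orig_id(n.id), n.node_type)]
                 for n in net2.nodes_by_type[t]]
            )
            for t in NodeType
        }
        m2, _ = train_discrete(net2, f2, arch, cfg)
        # transplant weights so both models share parameters
        for k, v in m1.weights.items():
            if k in m2.weights:
                m2.weights[k].data = v.data.copy()
            else:
                m2.weights[k] = v
        q, c, _ = hr.enumerate_candidate_pairs(net1, "circRNA").pairs[0]
        q2 = NodeRef("zz" + q.id[::-1], q.node_type)
        c2 = NodeRef("zz" + c.id[::-1], c.node_type)
        e1 = m1.embed_edges([(q, c)]).vectors[0]
        e2 = m2.embed_edges([(q2, c2)]).vectors[0]
        np.testing.assert_allclose(e1, e2, atol=1e-10)

    def test_checkpoint_roundtrip(self, trained_model, tmp_path):
        net, model = trained_model
        path = tmp_path / "ckpt.json"
        model.save(path)
        back = type(model).load(path)
        pairs = hr.enumerate_candidate_pairs(net, "circRNA").pairs[:10]
        np.testing.assert_allclose(
            model.embed_edges(pairs).vectors, back.embed_edges(pairs).vectors
        )


class TestEmbeddingSimilarity:
    def _table(self, vectors):
        pairs = [
            (NodeRef(f"r{i}", NodeType.CIRCRNA), NodeRef("c0", NodeType.CANCER))
            for i in range(len(vectors))
        ]
        return EdgeEmbeddingTable(pairs=pairs, vectors=np.asarray(vectors, float))

    def test_self_correlation_one(self):
        m = embedding_similarity_matrix(self._table([[1, 2, 3], [1, 2, 3]]))
        assert m[0, 1] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        m = embedding_similarity_matrix(self._table([[1, 2, 3], [3, 2, 1]]))
        assert m[0, 1] == pytest.approx(-1.0)

    def test_known_pearson_value(self):
        x, y = np.array([1.0, 2, 3]), np.array([1.0, 2, 4])
        expected = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        m = embedding_similarity_matrix(self._table([x, y]))
        assert m[0, 1] == pytest.approx(expected)
        assert m[0, 1] == pytest.approx(0.98198, abs=1e-5)

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(10)
        m = embedding_similarity_matrix(self._table(rng.normal(size=(6, 8))))
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert np.all((m >= -1) & (m <= 1))

    def test_zero_variance_embedding_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            embedding_similarity_matrix(self._table([[1.0, 1.0], [1.0, 2.0]]))
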