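import numpy as np
import pytest

import hetrank as hr


@pytest.fixture(scope="session")
def desk_net():
    """Desk-scale synthetic network (60 circRNAs / 12 drugs / 15 cancers)."""
    net, truth = hr.generate_hetnet(hr.desk_config(seed=11))
    return net, truth


@pytest.fixture(scope="session")
def table1_net():
    """Synthetic network at the published data scale (477 nodes, 2334 edges)."""
    net, truth = hr.generate_hetnet(hr.table1_config(seed=7))
    return net, truth


@pytest.fixture
def tiny_net():
    """Two circRNAs, one drug, two cancers; every node has degree >= 1."""
    from hetrank.hetnet import NodeRef, NodeType, Relation, TypedEdge

    r = lambda i: NodeRef(f"r{i}", NodeType.CIRCRNA)
    d = lambda i: NodeRef(f"d{i}", NodeType.DRUG)
    c = lambda i: NodeRef(f"c{i}", NodeType.CANCER)
    edges = [
        TypedEdge(r(1), c(1), Relation.CIRC_CANCER),
        TypedEdge(r(2), c(2), Relation.CIRC_CANCER),
        TypedEdge(r(1), d(1), Relation.CIRC_DRUG),
        TypedEdge(d(1), c(1), Relation.DRUG_CANCER),
    ]
    return hr.build_network(edges)


def random_ranking(rng, n, with_ties=False):
    """A random LabeledRanking for metric oracle checks."""
    labels = (rng.random(n) < 0.3).astype(float)
    scores = rng.random(n)
    if with_ties:
        scores = np.round(scores, 1)
    dids = [f"c{i:03d}" for i in range(n)]
    return hr.LabeledRanking(qid="q0", dids=dids, labels=labels, scores=scores)
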