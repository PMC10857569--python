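"""Listwise learning-to-rank with LambdaMART.

Gradient-boosted regression trees trained on LambdaRank gradients: for each
(relevant, non-relevant) document pair within a query, a logistic pairwise
gradient is weighted by the |ΔNDCG| of swapping the pair; trees fit these
pseudo-gradients with Newton-step leaf values, quantile threshold
candidates and a minimum leaf support, mirroring the classic RankLib
dialect — including its dataset format, which is read and written
bit-exactly here.

Ranking is per query: a circRNA or drug is the query (qid), candidate
cancers are the documents (did), and the feature vector of a document is
the learned edge embedding of the (query, cancer) pair.  All unobserved
pairs of a query enter its candidate list with label 0; no negative
subsampling is performed.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field, asdict

import numpy as np

MODEL_FORMAT_VERSION = 1


@dataclass
class RankingSample:
    label: int
    qid: str
    features: np.ndarray
    did: str


@dataclass
class RankingDataset:
    samples: list[RankingSample] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.samples[0].features) if self.samples else 0

    def matrix(self) -> np.ndarray:
        return np.array([s.features for s in self.samples], dtype=float)

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=float)

    def groups(self) -> dict[str, np.ndarray]:
        """qid -> sample indices, in first-appearance order of qids."""
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            out.setdefault(s.qid, []).append(i)
        return {q: np.array(ix, dtype=np.intp) for q, ix in out.items()}


@dataclass
class LambdaMartConfig:
    n_trees: int = 1000
    learning_rate: float = 0.1
    n_threshold_candidates: int = 256
    min_leaf_support: int = 1
    n_leaves: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_trees", "learning_rate", "n_threshold_candidates",
                     "min_leaf_support", "n_leaves"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RankedList:
    qid: str
    ranking: list[tuple[str, float]]  # (did, score) descending, ties by did


# ---------------------------------------------------------------------------
# RankLib-dialect I/O: `<label> qid:<qid> 1:<v1> 2:<v2> ... # did=<did>`
# ---------------------------------------------------------------------------

def write_ranklib(dataset: RankingDataset, path) -> None:
    width = dataset.n_features
    with open(path, "w") as fh:
        for s in dataset.samples:
            if len(s.features) != width:
                raise ValueError("inconsistent feature width")
            feats = " ".join(f"{j + 1}:{repr(float(v))}" for j, v in enumerate(s.features))
            fh.write(f"{int(s.label)} qid:{s.qid} {feats} # did={s.did}\n")


def read_ranklib(path) -> RankingDataset:
    samples: list[RankingSample] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            body, _, comment = line.partition("#")
            did = ""
            if comment.strip().startswith("did="):
                did = comment.strip()[4:]
            toks = body.split()
            try:
                label = int(toks[0])
                qid_tok = toks[1]
                assert qid_tok.startswith("qid:")
                qid = qid_tok[4:]
                feats: list[float] = []
                for j, tok in enumerate(toks[2:], start=1):
                    idx_s, _, val_s = tok.partition(":")
                    if int(idx_s) != j:
                        raise ValueError(
                            f"non-contiguous feature index {idx_s} (expected {j})"
                        )
                    feats.append(float(val_s))
            except (ValueError, AssertionError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable line: {exc}") from exc
            if width is None:
                width = len(feats)
            elif len(feats) != width:
                raise ValueError(
                    f"{path}:{lineno}: feature width {len(feats)} != {width}"
                )
            samples.append(
                RankingSample(label=label, qid=qid, features=np.array(feats), did=did)
            )
    return RankingDataset(samples=samples)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class RegressionTree:
    """Binary tree stored as parallel arrays; leaves have feature == -1."""

    feature: list[int]
    threshold: list[float]
    left: list[int]
    right: list[int]
    value: list[float]

    def predict(self, x: np.ndarray) -> np.ndarray:
        out = np.empty(len(x))
        node = np.zeros(len(x), dtype=np.intp)
        active = np.arange(len(x))
        while len(active):
            f = np.array([self.feature[n] for n in node[active]])
            leaf = f < 0
            for i in active[leaf]:
                out[i] = self.value[node[i]]
            active = active[~leaf]
            if not len(active):
                break
            nd = node[active]
            fs = np.array([self.feature[n] for n in nd])
            th = np.array([self.threshold[n] for n in nd])
            go_left = x[active, fs] <= th
            node[active] = np.where(
                go_left,
                [self.left[n] for n in nd],
                [self.right[n] for n in nd],
            )
        return out

    @property
    def n_leaves(self) -> int:
        return sum(1 for f in self.feature if f < 0)


@dataclass
class TreeEnsemble:
    trees: list[RegressionTree]
    shrinkage: float
    n_features: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"feature width {x.shape[1]} != training width {self.n_features}"
            )
        s = np.zeros(len(x))
        for t in self.trees:
            s += self.shrinkage * t.predict(x)
        return s

    def save(self, path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "shrinkage": self.shrinkage,
            "n_features": self.n_features,
            "trees": [asdict(t) for t in self.trees],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TreeEnsemble":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        return cls(
            trees=[RegressionTree(**t) for t in payload["trees"]],
            shrinkage=payload["shrinkage"],
            n_features=payload["n_features"],
        )


def _quantile_thresholds(col: np.ndarray, n_candidates: int) -> np.ndarray:
    """Equal-frequency split-point candidates, computed once before boosting."""
    uniq = np.unique(col)
    if len(uniq) <= 1:
        return np.array([])
    if len(uniq) - 1 <= n_candidates:
        return (uniq[:-1] + uniq[1:]) / 2.0
    qs = np.quantile(col, np.linspace(0, 1, n_candidates + 1)[1:-1])
    return np.unique(qs)


def _fit_tree(
    binned: np.ndarray,
    thresholds: list[np.ndarray],
    g: np.ndarray,
    h: np.ndarray,
    cfg: LambdaMartConfig,
) -> tuple[RegressionTree, np.ndarray]:
    """Best-first regression tree on second-order (g, h) statistics.

    Split gain GL^2/HL + GR^2/HR - G^2/H; leaves below ``min_leaf_support``
    documents are never created; Newton leaf value -G/H.
    """
    n, n_feat = binned.shape
    eps = 1e-10
    feature = [-1]
    threshold = [0.0]
    left = [-1]
    right = [-1]
    value = [-float(g.sum()) / (float(h.sum()) + eps)]
    leaf_rows: dict[int, np.ndarray] = {0: np.arange(n)}

    def best_split(rows: np.ndarray):
        gt, ht = g[rows].sum(), h[rows].sum()
        base = gt * gt / (ht + eps)
        best = (0.0, -1, -1)  # gain, feature, bin
        for j in range(n_feat):
            nb = len(thresholds[j]) + 1
            if nb <= 1:
                continue
            b = binned[rows, j]
            gh = np.bincount(b, weights=g[rows], minlength=nb)
            hh = np.bincount(b, weights=h[rows], minlength=nb)
            ch = np.bincount(b, minlength=nb)
            gl, hl, cl = np.cumsum(gh)[:-1], np.cumsum(hh)[:-1], np.cumsum(ch)[:-1]
            gr, hr, cr = gt - gl, ht - hl, len(rows) - cl
            ok = (cl >= cfg.min_leaf_support) & (cr >= cfg.min_leaf_support)
            if not ok.any():
                continue
            gain = np.where(
                ok, gl * gl / (hl + eps) + gr * gr / (hr + eps) - base, -np.inf
            )
            k = int(np.argmax(gain))
            if gain[k] > best[0]:
                best = (float(gain[k]), j, k)
        return best

    heap: list[tuple[float, int, int, int]] = []  # (-gain, tiebreak, leaf, ...)
    counter = 0

    def push(leaf: int) -> None:
        nonlocal counter
        gain, j, k = best_split(leaf_rows[leaf])
        if j >= 0 and gain > 0:
            heapq.heappush(heap, (-gain, counter, leaf, j, k))
            counter += 1

    push(0)
    n_leaves = 1
    while heap and n_leaves < cfg.n_leaves:
        _, _, leaf, j, k = heapq.heappop(heap)
        rows = leaf_rows.pop(leaf, None)
        if rows is None:
            continue
        go_left = binned[rows, j] <= k
        l_rows, r_rows = rows[go_left], rows[~go_left]
        li, ri = len(feature), len(feature) + 1
        for rws in (l_rows, r_rows):
            feature.append(-1)
            threshold.append(0.0)
            left.append(-1)
            right.append(-1)
            value.append(-float(g[rws].sum()) / (float(h[rws].sum()) + eps))
        feature[leaf] = j
        threshold[leaf] = float(thresholds[j][k])
        left[leaf], right[leaf] = li, ri
        value[leaf] = 0.0
        leaf_rows[li], leaf_rows[ri] = l_rows, r_rows
        n_leaves += 1
        push(li)
        push(ri)

    tree = RegressionTree(feature, threshold, left, right, value)
    pred = np.zeros(n)
    for leaf, rows in leaf_rows.items():
        pred[rows] = value[leaf]
    return tree, pred


# ---------------------------------------------------------------------------
# lambda gradients
# ---------------------------------------------------------------------------

def _rank_order(scores: np.ndarray, dids: list[str]) -> np.ndarray:
    """Descending by score, ties broken by did lexicographic order."""
    return np.array(
        sorted(range(len(scores)), key=lambda i: (-scores[i], dids[i])),
        dtype=np.intp,
    )


def _dcg_discounts(n: int) -> np.ndarray:
    return 1.0 / np.log2(np.arange(n) + 2.0)


def _lambdas_query(
    scores: np.ndarray, labels: np.ndarray, dids: list[str], sigma: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """LambdaRank first/second-order statistics for one query (binary gain
    2^label - 1, discount 1/log2(rank+1), |ΔNDCG| swap weighting)."""
    n = len(scores)
    lam = np.zeros(n)
    hess = np.zeros(n)
    pos = np.where(labels > 0)[0]
    neg = np.where(labels <= 0)[0]
    if len(pos) == 0 or len(neg) == 0:
        return lam, hess
    order = _rank_order(scores, dids)
    rank_of = np.empty(n, dtype=np.intp)
    rank_of[order] = np.arange(n)
    disc = _dcg_discounts(n)[rank_of]
    gains = 2.0 ** labels - 1.0
    ideal = np.sort(gains)[::-1]
    idcg = float((ideal * _dcg_discounts(n)).sum())
    if idcg <= 0:
        return lam, hess
    s_diff = scores[pos][:, None] - scores[neg][None, :]
    rho = 1.0 / (1.0 + np.exp(sigma * np.clip(s_diff, -60, 60)))
    delta = (
        np.abs(gains[pos][:, None] - gains[neg][None, :])
        * np.abs(disc[pos][:, None] - disc[neg][None, :])
        / idcg
    )
    lam_pair = sigma * rho * delta
    hess_pair = sigma * sigma * rho * (1.0 - rho) * delta
    lam[pos] += lam_pair.sum(axis=1)
    lam[neg] -= lam_pair.sum(axis=0)
    hess[pos] += hess_pair.sum(axis=1)
    hess[neg] += hess_pair.sum(axis=0)
    return lam, hess


def train_lambdamart(
    train: RankingDataset, cfg: LambdaMartConfig | None = None
) -> TreeEnsemble:
    """Boost ``cfg.n_trees`` regression trees on LambdaRank gradients."""
    cfg = cfg or LambdaMartConfig()
    if not len(train):
        raise ValueError("empty training set")
    groups = train.groups()
    labels = train.labels()
    learnable = any(
        labels[ix].max() != labels[ix].min() for ix in groups.values()
    )
    if not learnable:
        raise ValueError(
            "no learnable pairs: every query has identical labels"
        )
    x = train.matrix()
    dids = [s.did for s in train.samples]
    thresholds = [
        _quantile_thresholds(x[:, j], cfg.n_threshold_candidates)
        for j in range(x.shape[1])
    ]
    binned = np.stack(
        [
            np.searchsorted(thresholds[j], x[:, j], side="left")
            if len(thresholds[j])
            else np.zeros(len(x), dtype=np.intp)
            for j in range(x.shape[1])
        ],
        axis=1,
    ).astype(np.intp)
    scores = np.zeros(len(x))
    trees: list[RegressionTree] = []
    for _ in range(cfg.n_trees):
        g = np.zeros(len(x))
        h = np.zeros(len(x))
        for ix in groups.values():
            lam, hs = _lambdas_query(scores[ix], labels[ix], [dids[i] for i in ix])
            g[ix] -= lam  # gradient of the implicit loss is -lambda
            h[ix] += hs
        tree, pred = _fit_tree(binned, thresholds, g, h, cfg)
        trees.append(tree)
        scores += cfg.learning_rate * pred
    return TreeEnsemble(trees=trees, shrinkage=cfg.learning_rate, n_features=x.shape[1])


def predict_scores(model: TreeEnsemble, dataset: RankingDataset) -> list[RankedList]:
    """Score every sample and produce per-query rankings (descending score,
    ties broken by did lexicographic order)."""
    if not len(dataset):
        return []
    scores = model.predict(dataset.matrix())
    out: list[RankedList] = []
    for qid, ix in dataset.groups().items():
        dids = [dataset.samples[i].did for i in ix]
        order = _rank_order(scores[ix], dids)
        out.append(
            RankedList(
                qid=qid,
                ranking=[(dids[i], float(scores[ix][i])) for i in order],
            )
        )
    return out


def write_ranked_lists(lists: list[RankedList], path) -> None:
    """Output format: one `qid<TAB>did<TAB>score` row per candidate."""
    with open(path, "w") as fh:
        fh.write("qid\tdid\tscore\n")
        for rl in lists:
            for did, score in rl.ranking:
                fh.write(f"{rl.qid}\t{did}\t{repr(score)}\n")
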