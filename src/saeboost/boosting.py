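"""Reference gradient boosted trees.

A from-scratch implementation of Friedman-style gradient boosting with CART
base learners: start from the constant minimizer of the loss, then at each
round fit a regression tree to the negative gradient of the loss at the
current fit, set each terminal node to the (approximate) argmin of the loss
over its members, and add the tree scaled by the learning rate.

Two loss families are provided: squared error (regression; exact leaf
argmin = leaf mean of residuals) and logistic log-loss on the raw score
(binary classification; leaf argmin approximated by a one-step Newton
update, sum(y - p) / sum(p(1-p)), as is standard practice).

Missing feature values are treated as a splitting criterion: every split
candidate is evaluated with the missing block routed left and routed right,
and the node stores the winning default direction, so no imputation is
required.  Categorical features enter as level codes and are split
one-vs-rest.

The number of rounds can be chosen by early stopping on five-fold
cross-validated loss (:func:`select_rounds_by_cv`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-12


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass(frozen=True)
class LossFamily:
    """A differentiable loss with everything boosting needs: the value,
    the negative gradient, the constant initializer f_0, the per-leaf
    estimate rule, and the link from raw score to mean response."""

    name: str

    def value(self, y: np.ndarray, f: np.ndarray) -> np.ndarray:
        if self.name == "squared":
            return 0.5 * (y - f) ** 2
        return np.logaddexp(0.0, f) - y * f  # softplus(f) - y f

    def negative_gradient(self, y: np.ndarray, f: np.ndarray) -> np.ndarray:
        if self.name == "squared":
            return y - f
        return y - _sigmoid(f)

    def constant_init(self, y: np.ndarray) -> float:
        if self.name == "squared":
            return float(np.mean(y))
        p = float(np.clip(np.mean(y), _EPS, 1 - _EPS))
        return math.log(p / (1 - p))

    def leaf_estimate(self, y: np.ndarray, f_prev: np.ndarray) -> float:
        if self.name == "squared":
            return float(np.mean(y - f_prev))
        p = _sigmoid(f_prev)
        return float(np.sum(y - p) / max(np.sum(p * (1 - p)), _EPS))

    def mean_link(self, f: np.ndarray) -> np.ndarray:
        if self.name == "squared":
            return f
        return _sigmoid(f)


def loss_family(name: str) -> LossFamily:
    if name not in ("squared", "logistic"):
        raise ValueError(f"unknown loss {name!r}; expected 'squared' or 'logistic'")
    return LossFamily(name)


@dataclass
class GBTConfig:
    """Boosting hyperparameters.

    The unoptimized default is learning_rate=0.3 with n_rounds=50; the
    optimized variant uses learning_rate=0.1 with early stopping by
    five-fold cross-validation (rounds capped at ``max_rounds``, stopping
    after ``patience`` rounds without CV-loss improvement).  Tree size
    defaults (max_depth=6, min_leaf_size=20) mirror common booster defaults.
    """

    learning_rate: float = 0.3
    n_rounds: int = 50
    max_depth: int = 6
    min_leaf_size: int = 20
    loss: str = "squared"
    early_stopping: bool = False
    cv_folds: int = 5
    max_rounds: int = 500
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.n_rounds < 0 or self.max_depth < 1 or self.min_leaf_size < 1:
            raise ValueError("invalid tree/round configuration")


# ---------------------------------------------------------------------------
# CART with default-direction missing handling


@dataclass
class TreeNode:
    feature: int = -1          # -1 = leaf
    threshold: float = np.nan  # numeric split: x <= threshold goes left
    level: float = np.nan      # categorical split: code == level goes left
    missing_left: bool = True
    left: int = -1
    right: int = -1
    value: float = 0.0


class Tree:
    """A fitted CART stored as a flat node list (index 0 = root)."""

    def __init__(self, nodes: list[TreeNode], categorical: np.ndarray):
        self.nodes = nodes
        self.categorical = categorical

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Terminal node index per row; missing values follow each node's
        default direction."""
        out = np.zeros(len(X), dtype=np.int64)
        stack = [(0, np.arange(len(X)))]
        while stack:
            nid, rows = stack.pop()
            node = self.nodes[nid]
            if node.feature < 0:
                out[rows] = nid
                continue
            xv = X[rows, node.feature]
            miss = np.isnan(xv)
            if self.categorical[node.feature]:
                go_left = xv == node.level
            else:
                with np.errstate(invalid="ignore"):
                    go_left = xv <= node.threshold
            go_left = np.where(miss, node.missing_left, go_left)
            stack.append((node.left, rows[go_left]))
            stack.append((node.right, rows[~go_left]))
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        leaves = self.apply(X)
        values = np.array([n.value for n in self.nodes])
        return values[leaves]

    def leaf_ids(self) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.nodes) if n.feature < 0])


def _best_split(X, g, rows, categorical, min_leaf):
    """Exhaustive greedy split search at one node.

    Maximizes squared-error reduction sum_L²/n_L + sum_R²/n_R over every
    (feature, threshold | one-vs-rest level, missing direction) candidate.
    Ties broken toward the lowest feature index, then the lowest
    threshold/level, then routing missing left.  Returns None if no valid
    split improves on the parent.
    """
    g_node = g[rows]
    n_tot = rows.size
    s_tot = g_node.sum()
    parent = s_tot * s_tot / n_tot
    best = None  # (gain, feature, kind, split_value, missing_left)
    for j in range(X.shape[1]):
        xv = X[rows, j]
        miss = np.isnan(xv)
        n_m = int(miss.sum())
        xo, go = xv[~miss], g_node[~miss]
        if xo.size == 0:
            continue
        s_m = g_node[miss].sum()
        if categorical[j]:
            codes = xo.astype(np.int64)
            width = codes.max() + 1
            nl_all = np.bincount(codes, minlength=width).astype(float)
            sl_all = np.bincount(codes, weights=go, minlength=width)
            present = nl_all > 0
            cand_vals = np.nonzero(present)[0].astype(float)
            nl, sl = nl_all[present], sl_all[present]
        else:
            order = np.argsort(xo, kind="stable")
            xs, gs = xo[order], go[order]
            cut = np.nonzero(xs[:-1] < xs[1:])[0]
            if cut.size == 0:
                continue
            nl = (cut + 1).astype(float)
            sl = np.cumsum(gs)[cut]
            cand_vals = 0.5 * (xs[cut] + xs[cut + 1])
        nr = (n_tot - n_m) - nl
        sr = (s_tot - s_m) - sl

        with np.errstate(divide="ignore", invalid="ignore"):
            score_l = np.where(
                (nl + n_m >= min_leaf) & (nr >= min_leaf),
                (sl + s_m) ** 2 / (nl + n_m) + np.where(nr > 0, sr**2 / nr, 0.0),
                -np.inf,
            )
            score_r = np.where(
                (nl >= min_leaf) & (nr + n_m >= min_leaf),
                np.where(nl > 0, sl**2 / nl, 0.0) + (sr + s_m) ** 2 / (nr + n_m),
                -np.inf,
            )
        take_left = score_l >= score_r  # prefer routing missing left on ties
        score = np.where(take_left, score_l, score_r)
        i = int(np.argmax(score))  # first max = lowest threshold/level
        if score[i] == -np.inf:
            continue
        gain = score[i] - parent
        if best is None or gain > best[0] + 1e-12:
            best = (gain, j, categorical[j], float(cand_vals[i]), bool(take_left[i]))
    if best is None or best[0] <= 1e-12:
        return None
    return best


def fit_cart(
    X: np.ndarray,
    targets: np.ndarray,
    config: GBTConfig,
    categorical: np.ndarray | None = None,
) -> Tree:
    """Grow a regression tree on (possibly missing-valued) features.

    Depth-first greedy growth; leaves initially carry the mean target
    (boosting replaces them with the loss family's leaf estimate).
    """
    X = np.asarray(X, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("feature matrix must be 2-D and non-empty")
    if len(X) != len(targets):
        raise ValueError("features and targets length mismatch")
    if categorical is None:
        categorical = np.zeros(X.shape[1], dtype=bool)

    nodes: list[TreeNode] = []
    leaf_rows: dict[int, np.ndarray] = {}

    def grow(rows: np.ndarray, depth: int) -> int:
        nid = len(nodes)
        nodes.append(TreeNode(value=float(targets[rows].mean())))
        t = targets[rows]
        if (
            depth >= config.max_depth
            or rows.size < 2 * config.min_leaf_size
            or np.all(t == t[0])
        ):
            leaf_rows[nid] = rows
            return nid
        found = _best_split(X, targets, rows, categorical, config.min_leaf_size)
        if found is None:
            leaf_rows[nid] = rows
            return nid
        _, j, is_cat, split_value, missing_left = found
        xv = X[rows, j]
        miss = np.isnan(xv)
        if is_cat:
            go_left = xv == split_value
        else:
            with np.errstate(invalid="ignore"):
                go_left = xv <= split_value
        go_left = np.where(miss, missing_left, go_left)
        node = nodes[nid]
        node.feature = j
        node.missing_left = missing_left
        if is_cat:
            node.level = split_value
        else:
            node.threshold = split_value
        node.left = grow(rows[go_left], depth + 1)
        node.right = grow(rows[~go_left], depth + 1)
        return nid

    grow(np.arange(len(X)), 0)
    tree = Tree(nodes, categorical)
    tree._leaf_rows = leaf_rows  # training-row membership, used by boost()
    return tree


# ---------------------------------------------------------------------------
# boosting


class GBTModel:
    """An additive model f(x) = link(f_0 + alpha * sum_t tree_t(x)).

    Rows with every feature missing carry no information for any tree and
    receive the linked constant ``f_0``.
    """

    def __init__(self, f0: float, learning_rate: float, loss: LossFamily,
                 trees: list[Tree], categorical: np.ndarray):
        self.f0 = f0
        self.learning_rate = learning_rate
        self.loss = loss
        self.trees = trees
        self.categorical = categorical

    @property
    def n_rounds(self) -> int:
        return len(self.trees)

    def raw_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        raw = np.full(len(X), self.f0)
        for tree in self.trees:
            raw += self.learning_rate * tree.predict(X)
        all_missing = np.isnan(X).all(axis=1)
        raw[all_missing] = self.f0
        return raw

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Mean response: probability under logistic loss, value under
        squared loss."""
        return self.loss.mean_link(self.raw_scores(X))

    # -- plain-text serialization ------------------------------------------

    def to_json(self) -> str:
        def node_spec(n: TreeNode):
            if n.feature < 0:
                return {"value": n.value}
            return {
                "feature": n.feature,
                "threshold": None if math.isnan(n.threshold) else n.threshold,
                "level": None if math.isnan(n.level) else n.level,
                "missing_left": n.missing_left,
                "left": n.left,
                "right": n.right,
            }

        return json.dumps(
            {
                "f0": self.f0,
                "learning_rate": self.learning_rate,
                "loss": self.loss.name,
                "categorical": self.categorical.astype(int).tolist(),
                "trees": [[node_spec(n) for n in t.nodes] for t in self.trees],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GBTModel":
        spec = json.loads(text)
        categorical = np.array(spec["categorical"], dtype=bool)
        trees = []
        for tnodes in spec["trees"]:
            nodes = []
            for d in tnodes:
                if "feature" not in d:
                    nodes.append(TreeNode(value=d["value"]))
                else:
                    nodes.append(
                        TreeNode(
                            feature=d["feature"],
                            threshold=np.nan if d["threshold"] is None else d["threshold"],
                            level=np.nan if d["level"] is None else d["level"],
                            missing_left=d["missing_left"],
                            left=d["left"],
                            right=d["right"],
                        )
                    )
            trees.append(Tree(nodes, categorical))
        return cls(spec["f0"], spec["learning_rate"], loss_family(spec["loss"]),
                   trees, categorical)


def _boost_round(X, y, raw, loss, config, categorical):
    """One boosting round: fit a tree to the negative gradient and set its
    leaves by the loss family's estimate.  Mutates nothing; returns the tree
    (its training-leaf values already replaced)."""
    g = loss.negative_gradient(y, raw)
    tree = fit_cart(X, g, config, categorical)
    for nid, rows in tree._leaf_rows.items():
        tree.nodes[nid].value = loss.leaf_estimate(y[rows], raw[rows])
    return tree


def boost(
    X: np.ndarray,
    y: np.ndarray,
    config: GBTConfig,
    categorical: np.ndarray | None = None,
    n_rounds: int | None = None,
) -> GBTModel:
    """Fit the boosted model with a fixed number of rounds."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    loss = loss_family(config.loss)
    if loss.name == "logistic" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("logistic loss requires binary {0,1} labels")
    if categorical is None:
        categorical = np.zeros(X.shape[1], dtype=bool)
    T = config.n_rounds if n_rounds is None else n_rounds
    f0 = loss.constant_init(y)
    raw = np.full(len(y), f0)
    trees: list[Tree] = []
    for _ in range(T):
        tree = _boost_round(X, y, raw, loss, config, categorical)
        raw += config.learning_rate * tree.predict(X)
        trees.append(tree)
    return GBTModel(f0, config.learning_rate, loss, trees, categorical)


def best_round(mean_cv_losses) -> int:
    """Round (1-based) minimizing the mean cross-validated loss."""
    losses = np.asarray(mean_cv_losses, dtype=float)
    if losses.size == 0:
        raise ValueError("empty loss sequence")
    return int(np.argmin(losses)) + 1


def select_rounds_by_cv(
    X: np.ndarray,
    y: np.ndarray,
    config: GBTConfig,
    categorical: np.ndarray | None = None,
) -> tuple[int, np.ndarray]:
    """Choose the number of rounds by k-fold cross-validated loss.

    Folds are a seeded uniform shuffle of the training rows.  All folds are
    grown in lockstep; growth stops once the mean held-out loss has not
    improved for ``config.patience`` rounds (or at ``config.max_rounds``).
    Returns (T*, mean held-out loss per round).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    k = config.cv_folds
    if k < 2:
        raise ValueError("cv_folds must be >= 2")
    if len(y) < k:
        raise ValueError("fewer rows than folds")
    if categorical is None:
        categorical = np.zeros(X.shape[1], dtype=bool)
    loss = loss_family(config.loss)
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(y))
    folds = np.array_split(perm, k)

    states = []
    for val_idx in folds:
        train_idx = np.setdiff1d(perm, val_idx, assume_unique=False)
        f0 = loss.constant_init(y[train_idx])
        states.append(
            {
                "train": train_idx,
                "val": val_idx,
                "raw_train": np.full(train_idx.size, f0),
                "raw_val": np.full(val_idx.size, f0),
            }
        )

    mean_losses: list[float] = []
    best = np.inf
    since_best = 0
    for _ in range(config.max_rounds):
        val_loss = 0.0
        for st in states:
            tree = _boost_round(
                X[st["train"]], y[st["train"]], st["raw_train"], loss, config, categorical
            )
            st["raw_train"] += config.learning_rate * tree.predict(X[st["train"]])
            st["raw_val"] += config.learning_rate * tree.predict(X[st["val"]])
            val_loss += float(np.sum(loss.value(y[st["val"]], st["raw_val"])))
        mean_losses.append(val_loss / len(y))
        if mean_losses[-1] < best - 1e-12:
            best = mean_losses[-1]
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    return best_round(mean_losses), np.asarray(mean_losses)
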