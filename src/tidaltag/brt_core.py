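"""Boosted regression trees for a binomial response, built from scratch.

Stagewise gradient boosting with shallow least-squares regression trees:
each stage fits a tree to the current gradient residuals (y - p) on a
without-replacement subsample, terminal-node values take one Newton step on
the binomial deviance, and the ensemble grows by ``lr`` times each tree.
The number of trees is chosen by a stepwise k-fold cross-validation that
adds ``ss`` trees at a time and tracks mean held-out deviance.

Hyperparameters follow the conventions of ecological BRT practice:
*tree complexity* (tc, the interaction depth each tree may express),
*learning rate* (lr), *bag fraction* (bf) and *step size* (ss).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

_EPS = 1e-8


@dataclass(frozen=True)
class FitConfig:
    """Boosting hyperparameters and cross-validation controls."""

    tc: int = 3
    lr: float = 0.01
    bf: float = 0.7
    ss: int = 50
    n_folds: int = 10
    max_trees: int = 10_000
    min_obs_in_node: int = 10
    patience: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.tc < 1:
            raise ValueError("tc must be >= 1")
        if not 0 < self.lr <= 1:
            raise ValueError("lr must be in (0, 1]")
        if not 0 < self.bf <= 1:
            raise ValueError("bf must be in (0, 1]")
        if self.ss < 1 or self.n_folds < 2:
            raise ValueError("ss >= 1 and n_folds >= 2 required")


@dataclass
class TreeNode:
    """One node of a regression tree; terminal nodes carry a prediction."""

    prediction: float = 0.0
    split_var: int | None = None
    split_value: float | None = None
    improvement: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"prediction": self.prediction}
        return {
            "split_var": self.split_var,
            "split_value": self.split_value,
            "improvement": self.improvement,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "split_var" not in d:
            return cls(prediction=d["prediction"])
        return cls(
            split_var=d["split_var"],
            split_value=d["split_value"],
            improvement=d.get("improvement", 0.0),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


def _predict_tree(node: TreeNode, X: np.ndarray) -> np.ndarray:
    out = np.empty(len(X))
    stack = [(node, np.arange(len(X)))]
    while stack:
        nd, idx = stack.pop()
        if nd.is_leaf:
            out[idx] = nd.prediction
            continue
        go_left = X[idx, nd.split_var] <= nd.split_value
        stack.append((nd.left, idx[go_left]))
        stack.append((nd.right, idx[~go_left]))
    return out


def _best_split_sorted(X, z, orders, min_obs):
    """Least-squares split search over presorted per-feature row orders.

    ``orders[j]`` holds the node's row indices sorted by feature j.
    Returns (feature, threshold, improvement, split_pos) maximizing the
    squared-error reduction, or None.  Ties break on the lowest feature
    index, then the smallest threshold, so fits are reproducible.
    """
    n = len(orders[0])
    if n < 2 * min_obs:
        return None
    total = z[orders[0]].sum()
    nl = np.arange(1, n)
    best = None  # (-improvement, feature, threshold, split position)
    for j, oj in enumerate(orders):
        xs = X[oj, j]
        csum = np.cumsum(z[oj])[:-1]
        valid = (xs[1:] != xs[:-1]) & (nl >= min_obs) & ((n - nl) >= min_obs)
        if not valid.any():
            continue
        # improvement = SSE(parent) - SSE(children); constant terms cancel
        gain = csum**2 / nl + (total - csum) ** 2 / (n - nl) - total**2 / n
        gain = np.where(valid, gain, -np.inf)
        k = int(np.argmax(gain))
        if gain[k] <= 1e-12:
            continue
        thr = (xs[k] + xs[k + 1]) / 2.0
        if not (xs[k] <= thr < xs[k + 1]):  # float midpoint collapsed
            thr = xs[k]
        cand = (-gain[k], j, thr, k + 1)
        if best is None or cand[:3] < best[:3]:
            best = cand
    if best is None:
        return None
    return best[1], best[2], -best[0], best[3]


def fit_tree(X: np.ndarray, residuals: np.ndarray, config: FitConfig,
             idx: np.ndarray | None = None) -> TreeNode:
    """Greedy least-squares CART on gradient residuals, depth <= tc.

    Terminal predictions are node means of the residuals (the boosting loop
    replaces them with Newton-step values).  Identical residuals or no
    admissible split give a single leaf.  Feature orders are sorted once at
    the root and partitioned down the tree (order-preserving boolean
    indexing), which is what makes deep ensembles affordable.
    """
    X = np.asarray(X, dtype=float)
    z = np.asarray(residuals, dtype=float)
    if idx is None:
        idx = np.arange(len(X))
    root_orders = [idx[np.argsort(X[idx, j])] for j in range(X.shape[1])]
    in_left = np.zeros(len(X), dtype=bool)  # scratch, reused per split

    def grow(orders, depth: int) -> TreeNode:
        rows = orders[0]
        node = TreeNode(prediction=float(z[rows].mean()))
        if depth >= config.tc:
            return node
        found = _best_split_sorted(X, z, orders, config.min_obs_in_node)
        if found is None:
            return node
        j, thr, gain, pos = found
        node.split_var, node.split_value, node.improvement = j, thr, gain
        left_rows = orders[j][:pos]
        in_left[left_rows] = True
        left_orders = [o[in_left[o]] for o in orders]
        right_orders = [o[~in_left[o]] for o in orders]
        in_left[left_rows] = False
        node.left = grow(left_orders, depth + 1)
        node.right = grow(right_orders, depth + 1)
        return node

    return grow(root_orders, 0)


def _newton_leaf_values(node: TreeNode, X: np.ndarray, idx: np.ndarray,
                        y: np.ndarray, p: np.ndarray) -> None:
    """Replace leaf means with the one-step Newton estimate
    sum(y - p) / sum(p (1 - p)) over the leaf's training rows."""
    if node.is_leaf:
        num = (y[idx] - p[idx]).sum()
        den = (p[idx] * (1 - p[idx])).sum()
        node.prediction = float(num / max(den, _EPS))
        return
    go_left = X[idx, node.split_var] <= node.split_value
    _newton_leaf_values(node.left, X, idx[go_left], y, p)
    _newton_leaf_values(node.right, X, idx[~go_left], y, p)


@dataclass
class BoostedModel:
    """An ordered ensemble of shrunken regression trees plus intercept.

    Prediction is ``logistic(intercept + lr * sum of tree outputs)`` over
    the first ``n_trees_selected`` trees.
    """

    intercept: float
    trees: list[TreeNode]
    lr: float
    n_trees_selected: int
    predictor_names: list[str]
    config: FitConfig | None = None
    cv_curve: list[tuple[int, float]] = field(default_factory=list)

    def decision_function(self, X, n_trees: int | None = None) -> np.ndarray:
        X = _as_array(X, self.predictor_names)
        n = self.n_trees_selected if n_trees is None else n_trees
        F = np.full(len(X), self.intercept)
        for tree in self.trees[:n]:
            F += self.lr * _predict_tree(tree, X)
        return F

    def predict_proba(self, X, n_trees: int | None = None) -> np.ndarray:
        return _logistic(self.decision_function(X, n_trees))

    def to_json(self) -> str:
        return json.dumps({
            "intercept": self.intercept,
            "lr": self.lr,
            "n_trees_selected": self.n_trees_selected,
            "predictor_names": self.predictor_names,
            "config": asdict(self.config) if self.config else None,
            "cv_curve": self.cv_curve,
            "trees": [t.to_dict() for t in self.trees],
        })

    @classmethod
    def from_json(cls, s: str) -> "BoostedModel":
        d = json.loads(s)
        return cls(
            intercept=d["intercept"],
            trees=[TreeNode.from_dict(t) for t in d["trees"]],
            lr=d["lr"],
            n_trees_selected=d["n_trees_selected"],
            predictor_names=d["predictor_names"],
            config=FitConfig(**d["config"]) if d["config"] else None,
            cv_curve=[tuple(c) for c in d["cv_curve"]],
        )


@dataclass
class FitReport:
    """Training vs cross-validated discrimination and deviance explained."""

    t_auc: float
    cv_auc: float
    d2: float
    residual_deviance: float
    total_deviance: float

    @property
    def delta_auc(self) -> float:
        return self.t_auc - self.cv_auc

    @staticmethod
    def auc_band(auc: float) -> str:
        if auc < 0.6:
            return "fail"
        if auc < 0.7:
            return "poor"
        if auc < 0.8:
            return "acceptable"
        if auc < 0.9:
            return "excellent"
        return "outstanding"


def _logistic(F):
    return 1.0 / (1.0 + np.exp(-np.clip(F, -700, 700)))


def _as_array(X, names=None):
    if isinstance(X, pd.DataFrame):
        return (X[names] if names else X).to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _names(X):
    return list(X.columns) if isinstance(X, pd.DataFrame) else \
        [f"x{j}" for j in range(np.asarray(X).shape[1])]


def binomial_deviance(y, p) -> float:
    """Mean binomial deviance -2[y log p + (1-y) log(1-p)] (p clipped)."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1 - _EPS)
    if y.shape != p.shape:
        raise ValueError("y and p must have matching length")
    return float(np.mean(-2.0 * (y * np.log(p) + (1 - y) * np.log(1 - p))))


def auc_score(y, score) -> float:
    """Rank-based AUC (Mann-Whitney), ties counted one half."""
    y = np.asarray(y, dtype=float)
    score = np.asarray(score, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC needs both classes present")
    r = rankdata(score)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


class _Booster:
    """Incremental boosting state over a fixed training set."""

    def __init__(self, X, y, config: FitConfig, rng: np.random.Generator):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.y.min() == self.y.max():
            raise ValueError("response is constant; logit undefined")
        prevalence = self.y.mean()
        self.intercept = float(np.log(prevalence / (1 - prevalence)))
        self.F = np.full(len(self.y), self.intercept)
        self.config = config
        self.rng = rng
        self.trees: list[TreeNode] = []

    def grow(self, n_trees: int) -> None:
        cfg = self.config
        n = len(self.y)
        m = max(2 * cfg.min_obs_in_node, int(round(cfg.bf * n)))
        m = min(m, n)
        for _ in range(n_trees):
            p = _logistic(self.F)
            z = self.y - p
            sub = (self.rng.choice(n, size=m, replace=False)
                   if m < n else np.arange(n))
            tree = fit_tree(self.X, z, cfg, idx=np.sort(sub))
            _newton_leaf_values(tree, self.X, np.sort(sub), self.y, p)
            self.F += cfg.lr * _predict_tree(tree, self.X)
            self.trees.append(tree)

    def decision_function(self, X, n_trees: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n = len(self.trees) if n_trees is None else n_trees
        F = np.full(len(X), self.intercept)
        for tree in self.trees[:n]:
            F += self.config.lr * _predict_tree(tree, X)
        return F


def fit_brt(X, y, config: FitConfig, n_trees: int) -> BoostedModel:
    """Fit a boosted ensemble with a fixed number of trees."""
    names = _names(X)
    rng = np.random.default_rng(config.seed)
    booster = _Booster(_as_array(X), y, config, rng)
    booster.grow(n_trees)
    return BoostedModel(
        intercept=booster.intercept,
        trees=booster.trees,
        lr=config.lr,
        n_trees_selected=n_trees,
        predictor_names=names,
        config=config,
    )


def stratified_folds(y, n_folds: int, seed: int) -> np.ndarray:
    """Fold assignment per row, preserving class prevalence across folds."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    fold = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def step_cv_fit(X, y, config: FitConfig):
    """Stepwise cross-validated tree-count selection, then a full refit.

    Trees are added ``ss`` at a time to each fold's booster; mean held-out
    deviance is recorded per step.  Growth stops once the CV deviance has
    not improved for ``patience`` consecutive steps (or at ``max_trees``);
    the tree count at the CV-deviance minimum is then used to refit on all
    rows.  Returns the refit model, with the CV curve and fold assignment
    attached, plus the per-fold boosters for held-out evaluation.
    """
    Xa, ya = _as_array(X), np.asarray(y, dtype=float)
    if len(Xa) < 10 * config.n_folds:
        raise ValueError("too few rows for stepwise cross-validation")
    names = _names(X)
    fold = stratified_folds(ya, config.n_folds, config.seed)
    boosters = []
    for k in range(config.n_folds):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, k]))
        boosters.append(_Booster(Xa[fold != k], ya[fold != k], config, rng))

    curve: list[tuple[int, float]] = []
    best_dev, best_n, since_best = np.inf, 0, 0
    n_trees = 0
    while n_trees < config.max_trees:
        step = min(config.ss, config.max_trees - n_trees)
        for k, b in enumerate(boosters):
            b.grow(step)
        n_trees += step
        devs = [
            binomial_deviance(ya[fold == k],
                              _logistic(b.decision_function(Xa[fold == k])))
            for k, b in enumerate(boosters)
        ]
        mean_dev = float(np.mean(devs))
        curve.append((n_trees, mean_dev))
        if mean_dev < best_dev - 1e-12:
            best_dev, best_n, since_best = mean_dev, n_trees, 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_n == 0:
        raise ValueError("cross-validation selected zero trees")

    model = fit_brt(X, y, config, best_n)
    model.cv_curve = curve
    model.predictor_names = names
    return model, boosters, fold


def evaluate(model: BoostedModel, X, y, boosters=None, fold=None) -> FitReport:
    """Training AUC, mean held-out AUC, their gap, and deviance explained.

    ``boosters``/``fold`` from :func:`step_cv_fit` supply the held-out
    predictions; folds that end up single-class are skipped with a warning.
    D^2 = 1 - residual/total deviance, total from the intercept-only model.
    """
    ya = np.asarray(y, dtype=float)
    p_train = model.predict_proba(X)
    t_auc = auc_score(ya, p_train)
    cv_aucs = []
    if boosters is not None and fold is not None:
        Xa = _as_array(X, model.predictor_names)
        for k, b in enumerate(boosters):
            yk = ya[fold == k]
            if yk.min() == yk.max():
                logger.warning("fold %d is single-class; skipped in CV AUC", k)
                continue
            Fk = b.decision_function(Xa[fold == k], model.n_trees_selected)
            cv_aucs.append(auc_score(yk, _logistic(Fk)))
    cv_auc = float(np.mean(cv_aucs)) if cv_aucs else np.nan
    resid = binomial_deviance(ya, p_train)
    prevalence = ya.mean()
    total = binomial_deviance(ya, np.full(len(ya), prevalence))
    return FitReport(
        t_auc=t_auc,
        cv_auc=cv_auc,
        d2=1.0 - resid / total,
        residual_deviance=resid,
        total_deviance=total,
    )


TC_SET = (1, 2, 3, 4, 5, 6)
LR_SET = (0.01, 0.005, 0.001, 0.0001)
BF_SET = (0.5, 0.7, 0.9)
SS_SET = (25, 50)


def grid_configs(tc_set=TC_SET, lr_set=LR_SET, bf_set=BF_SET, ss_set=SS_SET,
                 **common) -> list[FitConfig]:
    """Cartesian product of the hyperparameter sets as FitConfigs."""
    return [
        FitConfig(tc=tc, lr=lr, bf=bf, ss=ss, **common)
        for tc, lr, bf, ss in itertools.product(tc_set, lr_set, bf_set, ss_set)
    ]


def grid_search(X, y, tc_set=TC_SET, lr_set=LR_SET, bf_set=BF_SET,
                ss_set=SS_SET, **common) -> pd.DataFrame:
    """Fit every hyperparameter combination; rank by CV AUC then gap.

    Returns one row per configuration with tc/lr/bf/ss and the fit metrics,
    sorted by cross-validated AUC descending with the training-CV gap
    (overfitting gauge) as tiebreak.
    """
    rows = []
    for cfg in grid_configs(tc_set, lr_set, bf_set, ss_set, **common):
        model, boosters, fold = step_cv_fit(X, y, cfg)
        rep = evaluate(model, X, y, boosters, fold)
        rows.append({
            "tc": cfg.tc, "lr": cfg.lr, "bf": cfg.bf, "ss": cfg.ss,
            "n_trees": model.n_trees_selected,
            "t_auc": rep.t_auc, "cv_auc": rep.cv_auc,
            "delta_auc": rep.delta_auc, "d2": rep.d2,
        })
    table = pd.DataFrame(rows)
    return table.sort_values(["cv_auc", "delta_auc"],
                             ascending=[False, True]).reset_index(drop=True)
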