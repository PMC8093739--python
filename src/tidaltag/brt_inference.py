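"""Interpretation of fitted boosted models.

Relative influence (split-improvement attribution), partial-dependence
profiles with bootstrap confidence bands, pairwise interaction strength on
a two-way quantile lattice, and a permutation test of interaction
significance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import brt_core
from .brt_core import BoostedModel, FitConfig, _as_array, _logistic
from ._util import child_seed

logger = logging.getLogger(__name__)


@dataclass
class PDCurve:
    """A partial-dependence profile, optionally with a bootstrap band."""

    predictor: str
    grid: np.ndarray
    response: np.ndarray  # probability scale
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None


@dataclass
class InteractionResult:
    """Observed pairwise interaction size with its permutation null."""

    pair: tuple[str, str]
    size: float
    null_sizes: np.ndarray
    p_value: float


def _collect_improvements(node, totals):
    if node.is_leaf:
        return
    totals[node.split_var] += node.improvement
    _collect_improvements(node.left, totals)
    _collect_improvements(node.right, totals)


def relative_influence(model: BoostedModel) -> pd.Series:
    """Percent influence per predictor, summing to 100.

    Each predictor is credited with the squared-error improvement of every
    split it provides across the selected trees, normalized to percentages.
    A model with no informative split gets a uniform table with a warning.
    """
    p = len(model.predictor_names)
    totals = np.zeros(p)
    for tree in model.trees[: model.n_trees_selected]:
        _collect_improvements(tree, totals)
    if totals.sum() <= 0:
        warnings.warn("model has no informative splits; uniform influence")
        totals = np.ones(p)
    return pd.Series(100.0 * totals / totals.sum(), index=model.predictor_names)


def _quantile_grid(x: np.ndarray, n_grid: int) -> np.ndarray:
    # trimmed to the central 95% so the lattice stays on the data manifold;
    # fitted surfaces are unconstrained beyond the extreme observations
    return np.quantile(x, np.linspace(0.025, 0.975, n_grid))


def partial_dependence(model: BoostedModel, predictor: str, X,
                       n_grid: int = 100, others: str = "mean") -> PDCurve:
    """Fitted response as one predictor sweeps a quantile lattice.

    ``others="mean"`` (default) holds every other predictor at its column
    mean — the at-means profile used for published dependency plots.
    ``others="marginal"`` instead averages predictions over all observed
    rows (the data-marginalizing partial dependence); the two agree exactly
    for additive models.
    """
    if predictor not in model.predictor_names:
        raise KeyError(f"unknown predictor {predictor!r}")
    Xa = _as_array(X, model.predictor_names)
    j = model.predictor_names.index(predictor)
    grid = _quantile_grid(Xa[:, j], n_grid)
    if others == "mean":
        base = Xa.mean(axis=0)
        pts = np.tile(base, (len(grid), 1))
        pts[:, j] = grid
        resp = _logistic(model.decision_function(pts))
    elif others == "marginal":
        # averaged on the link scale (Friedman-style), so additive models
        # give profiles identical to the at-means sweep up to a constant
        resp = np.empty(len(grid))
        for k, g in enumerate(grid):
            Xg = Xa.copy()
            Xg[:, j] = g
            resp[k] = _logistic(model.decision_function(Xg).mean())
    else:
        raise ValueError("others must be 'mean' or 'marginal'")
    return PDCurve(predictor=predictor, grid=grid, response=resp)


def pd_bootstrap(X, y, config: FitConfig, n_trees: int, predictor: str,
                 n_boot: int = 1000, level: float = 95.0,
                 n_grid: int = 50, seed: int = 0,
                 max_retries: int = 20) -> PDCurve:
    """Case-resampling bootstrap band around the at-means profile.

    Each replicate resamples rows with replacement, refits with the same
    configuration and tree count, and evaluates its profile on the original
    quantile grid; the band is the pointwise percentile interval, widened
    where needed to contain the point curve.  Single-class resamples are
    redrawn (capped at ``max_retries`` per replicate).
    """
    point_model = brt_core.fit_brt(X, y, config, n_trees)
    point = partial_dependence(point_model, predictor, X, n_grid=n_grid)
    Xa = _as_array(X, point_model.predictor_names)
    ya = np.asarray(y, dtype=float)
    j = point_model.predictor_names.index(predictor)
    rng = np.random.default_rng(seed)
    curves = np.empty((n_boot, n_grid))
    for b in range(n_boot):
        for attempt in range(max_retries):
            rows = rng.integers(0, len(ya), size=len(ya))
            if ya[rows].min() != ya[rows].max():
                break
        else:
            raise RuntimeError("could not draw a two-class resample")
        cfg_b = FitConfig(**{**config.__dict__,
                             "seed": child_seed(config.seed, 1000 + b)})
        mb = brt_core.fit_brt(Xa[rows], ya[rows], cfg_b, n_trees)
        base = Xa[rows].mean(axis=0)
        pts = np.tile(base, (n_grid, 1))
        pts[:, j] = point.grid
        curves[b] = _logistic(mb.decision_function(pts))
    alpha = (100.0 - level) / 2.0
    lower = np.minimum(np.percentile(curves, alpha, axis=0), point.response)
    upper = np.maximum(np.percentile(curves, 100 - alpha, axis=0),
                       point.response)
    return PDCurve(predictor=predictor, grid=point.grid,
                   response=point.response, lower=lower, upper=upper)


def interaction_strength(model: BoostedModel, pair: tuple[str, str], X,
                         n_grid: int = 20) -> float:
    """Departure of the fitted pair surface from additivity.

    The model is evaluated on an ``n_grid`` x ``n_grid`` quantile lattice of
    the two predictors (others at their means, on the linked/logit scale);
    a main-effects-only surface (grand mean + row effect + column effect)
    is fit by least squares, and the size is 1000 x the mean squared
    residual.  Additive models score ~0; the statistic is symmetric in its
    arguments by construction.
    """
    a, b = pair
    for name in pair:
        if name not in model.predictor_names:
            raise KeyError(f"unknown predictor {name!r}")
    Xa = _as_array(X, model.predictor_names)
    ja = model.predictor_names.index(a)
    jb = model.predictor_names.index(b)
    ga = _quantile_grid(Xa[:, ja], n_grid)
    gb = _quantile_grid(Xa[:, jb], n_grid)
    base = Xa.mean(axis=0)
    pts = np.tile(base, (n_grid * n_grid, 1))
    AA, BB = np.meshgrid(ga, gb, indexing="ij")
    pts[:, ja] = AA.ravel()
    pts[:, jb] = BB.ravel()
    surface = model.decision_function(pts).reshape(n_grid, n_grid)
    if np.ptp(surface) < 1e-12:
        return 0.0
    grand = surface.mean()
    row = surface.mean(axis=1, keepdims=True) - grand
    col = surface.mean(axis=0, keepdims=True) - grand
    resid = surface - (grand + row + col)
    return float(1000.0 * np.mean(resid**2))


def interaction_table(model: BoostedModel, X, n_grid: int = 20) -> pd.DataFrame:
    """Interaction size for every predictor pair, largest first.

    All pair lattices are stacked into one ensemble evaluation, which is
    much faster than per-pair calls for large tree counts.
    """
    names = model.predictor_names
    Xa = _as_array(X, names)
    base = Xa.mean(axis=0)
    grids = {n: _quantile_grid(Xa[:, j], n_grid)
             for j, n in enumerate(names)}
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    blocks = []
    for a, b in pairs:
        pts = np.tile(base, (n_grid * n_grid, 1))
        AA, BB = np.meshgrid(grids[a], grids[b], indexing="ij")
        pts[:, names.index(a)] = AA.ravel()
        pts[:, names.index(b)] = BB.ravel()
        blocks.append(pts)
    F = model.decision_function(np.vstack(blocks))
    rows = []
    for k, (a, b) in enumerate(pairs):
        surface = F[k * n_grid**2:(k + 1) * n_grid**2].reshape(n_grid, n_grid)
        if np.ptp(surface) < 1e-12:
            size = 0.0
        else:
            grand = surface.mean()
            row = surface.mean(axis=1, keepdims=True) - grand
            col = surface.mean(axis=0, keepdims=True) - grand
            size = float(1000.0 * np.mean((surface - grand - row - col) ** 2))
        rows.append({"predictor_1": a, "predictor_2": b, "size": size})
    return (pd.DataFrame(rows)
            .sort_values("size", ascending=False)
            .reset_index(drop=True))


def interaction_significance(X, y, pair: tuple[str, str], config: FitConfig,
                             n_trees: int, n_null: int = 100,
                             n_grid: int = 20, seed: int = 0,
                             observed_size: float | None = None
                             ) -> InteractionResult:
    """Permutation test of a pairwise interaction.

    The null distribution refits the model ``n_null`` times with the
    response randomly permuted (breaking any predictor-response structure)
    and recomputes the interaction size each time;
    p = (1 + #{null >= observed}) / (n_null + 1).
    """
    ya = np.asarray(y, dtype=float)
    if observed_size is None:
        model = brt_core.fit_brt(X, ya, config, n_trees)
        observed_size = interaction_strength(model, pair, X, n_grid)
    rng = np.random.default_rng(seed)
    Xa = _as_array(X)
    names = brt_core._names(X)
    null_sizes = np.empty(n_null)
    for r in range(n_null):
        y_perm = rng.permutation(ya)
        cfg_r = FitConfig(**{**config.__dict__,
                             "seed": child_seed(config.seed, 2000 + r)})
        m = brt_core.fit_brt(pd.DataFrame(Xa, columns=names), y_perm,
                             cfg_r, n_trees)
        null_sizes[r] = interaction_strength(m, pair, X, n_grid)
    p = (1.0 + (null_sizes >= observed_size).sum()) / (n_null + 1.0)
    return InteractionResult(pair=pair, size=float(observed_size),
                             null_sizes=null_sizes, p_value=float(p))
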