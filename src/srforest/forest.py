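"""Honest survival random forest for heterogeneous RMST.

Each tree is grown on a subsample drawn without replacement from a random
half of the training data.  The subsample is split into a *structure*
part ``J_b`` (chooses the splits) and a disjoint *estimation* part
``I_b`` (populates the leaves), making the tree honest.  Splits are
chosen by the estimating-equation pseudo-outcome criterion: at a parent
node with IPCW weights ``w`` and local solution
``μ̂_P = Σ w_i ZL_i / Σ w_i`` each observation carries its influence
value

    ρ_i = w_i (ZL_i − μ̂_P) / (Σ_{j∈P} w_j / |P|)

and the split maximizes ``Σ_{child} (Σ_{i∈child} ρ_i)² / |child|``, the
standard proxy for the decrease in squared estimation error of the local
parameter.  Forest weights aggregate leaf co-membership across trees and
the RMST prediction solves the locally weighted estimating equation in
closed form:

    μ̂ᴸ(x) = Σ_i α_i(x) ŵ_i ZL_i / Σ_i α_i(x) ŵ_i ,

with ŵ from a censoring model fitted on the full sample.  Trees are
organised in groups sharing one half-sample each, which the variance
module exploits for half-sampling (little bags) confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import warnings

import numpy as np

from .data import RestrictedDataset
from .ipcw import (
    CensoringModel,
    DEFAULT_WEIGHT_FLOOR,
    IpcwWeights,
    compute_ipcw,
    fit_cox_censoring,
)

__all__ = [
    "ForestConfig",
    "HonestTree",
    "SurvivalForest",
    "ForestWeights",
    "beta_min",
    "leaf_solution",
    "pseudo_outcomes",
    "best_split",
    "build_tree",
    "fit_forest",
    "forest_weights",
    "predict_rmst",
]


def beta_min(omega: float, pi: float) -> float:
    """Smallest admissible subsampling exponent for asymptotic normality.

    ``β_min = 1 − (1 + π⁻¹·log(1/ω)/log(1/(1−ω)))⁻¹`` where ω is the
    minimum child fraction at every split and π the per-feature split
    probability lower bound.
    """
    if not 0 < omega <= 0.5:
        raise ValueError(f"omega must lie in (0, 0.5], got {omega}")
    if not 0 < pi <= 1:
        raise ValueError(f"pi must lie in (0, 1], got {pi}")
    ratio = math.log(1.0 / omega) / math.log(1.0 / (1.0 - omega))
    return 1.0 - 1.0 / (1.0 + ratio / pi)


@dataclass(frozen=True)
class ForestConfig:
    """Hyperparameters of the honest survival forest.

    ``subsample_exponent`` sets the per-tree subsample size
    ``s = ⌈(n/2)^β⌉`` drawn without replacement from the tree's
    half-sample (an explicit ``subsample_size`` overrides it).
    ``group_size`` trees share each half-sample; the number of groups
    ``G = num_trees / group_size`` drives the variance estimator.
    """

    num_trees: int = 2000
    subsample_exponent: float = 0.85
    subsample_size: int | None = None
    honesty_fraction: float = 0.5
    min_node_size: int = 5
    mtry: int | None = None
    omega: float = 0.05
    split_prob_floor: float | None = None  # π; defaults to 1/p
    group_size: int = 2
    seed: int = 0
    weight_floor: float = DEFAULT_WEIGHT_FLOOR
    validate_exponent: bool = True

    def __post_init__(self):
        if self.num_trees < 1:
            raise ValueError("num_trees must be positive")
        if self.group_size < 2:
            raise ValueError("group_size must be >= 2")
        if self.num_trees % self.group_size != 0:
            raise ValueError(
                f"num_trees ({self.num_trees}) must be divisible by "
                f"group_size ({self.group_size})"
            )
        if not 0 < self.honesty_fraction < 1:
            raise ValueError("honesty_fraction must lie in (0, 1)")
        if not 0 < self.omega <= 0.5:
            raise ValueError("omega must lie in (0, 0.5]")
        if self.subsample_size is None and not 0 < self.subsample_exponent < 1:
            raise ValueError("subsample_exponent must lie in (0, 1)")

    def resolve(self, n: int, p: int) -> "ResolvedConfig":
        n_half = n // 2
        s = self.subsample_size or math.ceil(n_half ** self.subsample_exponent)
        s = min(s, n_half)
        mtry = self.mtry or min(math.ceil(math.sqrt(p)) + 2, p)
        if not 1 <= mtry <= p:
            raise ValueError(f"mtry must lie in [1, {p}], got {mtry}")
        if s < 2 * self.min_node_size:
            raise ValueError(
                f"subsample size {s} below 2*min_node_size "
                f"({2 * self.min_node_size}); increase n or the exponent"
            )
        pi = self.split_prob_floor or 1.0 / p
        if self.validate_exponent and self.subsample_size is None:
            bm = beta_min(self.omega, pi)
            if self.subsample_exponent <= bm:
                warnings.warn(
                    f"subsample exponent {self.subsample_exponent} does not "
                    f"exceed beta_min(omega={self.omega}, pi={pi:.3g}) = "
                    f"{bm:.4f}; the normality theory is not guaranteed",
                    stacklevel=2,
                )
        return ResolvedConfig(base=self, s=s, mtry=mtry, pi=pi, n=n, p=p)


@dataclass(frozen=True)
class ResolvedConfig:
    base: ForestConfig
    s: int
    mtry: int
    pi: float
    n: int
    p: int


@dataclass
class HonestTree:
    """Array-encoded honest tree.

    ``feature[k] == -1`` marks a leaf; internal nodes route
    ``x[feature] <= threshold`` to ``left``.  Leaves slice into
    ``members`` (estimation-sample subject indices) via
    ``leaf_start/leaf_count``.  Aggregates over leaf members with the
    full-data IPCW weights (filled in by the forest after growing) give
    O(1) per-leaf prediction terms.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_start: np.ndarray
    leaf_count: np.ndarray
    members: np.ndarray           # estimation indices grouped by leaf
    structure_indices: np.ndarray  # J_b
    estimation_indices: np.ndarray  # I_b
    group_id: int
    # per-leaf aggregates with full-data weights (set by fit_forest)
    leaf_sum_w: np.ndarray = field(default=None)
    leaf_sum_wz: np.ndarray = field(default=None)

    @property
    def n_nodes(self) -> int:
        return self.feature.shape[0]

    def leaf_for(self, Xq: np.ndarray) -> np.ndarray:
        """Vectorised routing of query rows to node indices of their leaf."""
        Xq = np.atleast_2d(Xq)
        idx = np.zeros(Xq.shape[0], dtype=np.int32)
        while True:
            f = self.feature[idx]
            active = f >= 0
            if not active.any():
                return idx
            rows = np.flatnonzero(active)
            fa = f[rows]
            go_left = Xq[rows, fa] <= self.threshold[idx[rows]]
            idx[rows] = np.where(
                go_left, self.left[idx[rows]], self.right[idx[rows]]
            )

    def leaf_members(self, node: int) -> np.ndarray:
        s, c = self.leaf_start[node], self.leaf_count[node]
        return self.members[s : s + c]


def leaf_solution(weights: np.ndarray, zL: np.ndarray) -> float:
    """Closed-form solution ``Σ w z / Σ w`` of the node estimating equation."""
    sw = float(np.sum(weights))
    if sw <= 0:
        raise ZeroDivisionError("all node weights are zero (degenerate node)")
    return float(np.dot(weights, zL) / sw)


def pseudo_outcomes(weights: np.ndarray, zL: np.ndarray, muP: float) -> np.ndarray:
    """Influence values ``ρ_i = w_i(z_i − μ̂_P)/(Σ w/|P|)``; they sum to 0."""
    denom = float(np.mean(weights))
    if denom <= 0:
        return np.zeros_like(zL)
    return weights * (zL - muP) / denom


def best_split(
    Xnode: np.ndarray,
    rho: np.ndarray,
    candidate_features: np.ndarray,
    min_child: int,
):
    """Exhaustive scan for the pseudo-outcome split criterion.

    Returns ``(feature, threshold, criterion)`` maximizing
    ``(Σ_left ρ)²/|left| + (Σ_right ρ)²/|right|`` over midpoint thresholds
    that leave at least ``min_child`` structure points in each child, or
    ``None`` when no admissible split has positive criterion.  Ties break
    toward the lowest feature index, then the lowest threshold.
    """
    m = rho.shape[0]
    best = None
    best_crit = 0.0
    for f in np.sort(candidate_features):
        xv = Xnode[:, f]
        order = np.argsort(xv, kind="stable")
        xs = xv[order]
        cums = np.cumsum(rho[order])
        total = cums[-1]
        k = np.arange(1, m)  # left child size
        valid = (k >= min_child) & (m - k >= min_child) & (xs[:-1] < xs[1:])
        if not valid.any():
            continue
        crit = np.where(
            valid,
            cums[:-1] ** 2 / k + (total - cums[:-1]) ** 2 / (m - k),
            -np.inf,
        )
        j = int(np.argmax(crit))
        if crit[j] > best_crit:
            best_crit = float(crit[j])
            best = (int(f), float(0.5 * (xs[j] + xs[j + 1])), best_crit)
    return best


def _grow(X, zL, w, local_idx, cfg: ResolvedConfig, rng, nodes):
    """Recursively grow structure; returns the node id."""
    node_id = len(nodes["feature"])
    nodes["feature"].append(-1)
    nodes["threshold"].append(np.nan)
    nodes["left"].append(-1)
    nodes["right"].append(-1)
    nodes["leaf_local"].append(local_idx)

    m = local_idx.shape[0]
    base = cfg.base
    if m < 2 * base.min_node_size:
        return node_id
    wn = w[local_idx]
    zn = zL[local_idx]
    sw = wn.sum()
    if sw <= 0:
        return node_id  # degenerate: all node weights zero
    muP = float(np.dot(wn, zn) / sw)
    rho = pseudo_outcomes(wn, zn, muP)
    if np.ptp(rho) == 0.0:
        return node_id
    feats = rng.choice(cfg.p, size=cfg.mtry, replace=False)
    min_child = max(base.min_node_size, math.ceil(base.omega * m))
    split = best_split(X[local_idx], rho, feats, min_child)
    if split is None:
        return node_id
    f, thr, _ = split
    go_left = X[local_idx, f] <= thr
    left_id = _grow(X, zL, w, local_idx[go_left], cfg, rng, nodes)
    right_id = _grow(X, zL, w, local_idx[~go_left], cfg, rng, nodes)
    nodes["feature"][node_id] = f
    nodes["threshold"][node_id] = thr
    nodes["left"][node_id] = left_id
    nodes["right"][node_id] = right_id
    nodes["leaf_local"][node_id] = None
    return node_id


def build_tree(
    rdata: RestrictedDataset,
    half_sample: np.ndarray,
    cfg: ResolvedConfig,
    rng: np.random.Generator,
    group_id: int = 0,
) -> HonestTree:
    """Grow one honest tree from a group's half-sample.

    Draws ``s`` subjects without replacement, splits them into structure
    (``J_b``) and estimation (``I_b``) parts, fits the censoring Cox
    model on ``J_b`` only, grows the structure by recursive pseudo-outcome
    splitting, then routes ``I_b`` into the leaves.
    """
    base = cfg.base
    sub = rng.choice(half_sample, size=cfg.s, replace=False)
    n_struct = max(1, int(round(base.honesty_fraction * cfg.s)))
    if n_struct >= cfg.s:
        raise ValueError("honesty split leaves no estimation points")
    J = sub[:n_struct]
    I = sub[n_struct:]

    cens = fit_cox_censoring(rdata.base, J)
    rJ = RestrictedDataset(
        base=rdata.base.subset(J),
        L=rdata.L,
        ZL=rdata.ZL[J],
        deltaL=rdata.deltaL[J],
    )
    wJ = compute_ipcw(rJ, cens, floor=base.weight_floor).w

    nodes = {
        "feature": [],
        "threshold": [],
        "left": [],
        "right": [],
        "leaf_local": [],
    }
    _grow(rdata.X[J], rdata.ZL[J], wJ, np.arange(J.shape[0]), cfg, rng, nodes)

    feature = np.asarray(nodes["feature"], dtype=np.int32)
    tree = HonestTree(
        feature=feature,
        threshold=np.asarray(nodes["threshold"], dtype=float),
        left=np.asarray(nodes["left"], dtype=np.int32),
        right=np.asarray(nodes["right"], dtype=np.int32),
        leaf_start=np.zeros(feature.shape[0], dtype=np.int32),
        leaf_count=np.zeros(feature.shape[0], dtype=np.int32),
        members=np.empty(0, dtype=np.int64),
        structure_indices=J,
        estimation_indices=I,
        group_id=group_id,
    )
    # populate leaves with the estimation sample
    leaf_nodes = tree.leaf_for(rdata.X[I])
    order = np.argsort(leaf_nodes, kind="stable")
    tree.members = I[order]
    uniq, start, cnt = np.unique(
        leaf_nodes[order], return_index=True, return_counts=True
    )
    tree.leaf_start[uniq] = start.astype(np.int32)
    tree.leaf_count[uniq] = cnt.astype(np.int32)
    return tree


@dataclass
class SurvivalForest:
    """Fitted honest survival forest (trees + prediction-time IPCW)."""

    trees: list[HonestTree]
    config: ForestConfig
    resolved: ResolvedConfig
    rdata: RestrictedDataset
    censoring_model: CensoringModel
    weights: IpcwWeights  # full-data prediction IPCW

    @property
    def num_groups(self) -> int:
        return self.config.num_trees // self.config.group_size

    @property
    def L(self) -> float:
        return self.rdata.L

    def predict(self, Xq: np.ndarray, return_psi: bool = False):
        """μ̂ᴸ(x) for each query row; optionally the per-tree Ψ matrix.

        Per tree the leaf containing x contributes its estimation-sample
        aggregates; trees whose leaf holds no estimation point are
        excluded and the averaging count adjusted, keeping the implicit
        forest weights a probability distribution.
        """
        Xq = np.atleast_2d(np.asarray(Xq, float))
        nq = Xq.shape[0]
        num = np.zeros(nq)
        den = np.zeros(nq)
        contributing = np.zeros(nq, dtype=np.int32)
        leaf_hits = np.empty((len(self.trees), nq), dtype=np.int32)
        for b, tree in enumerate(self.trees):
            lidx = tree.leaf_for(Xq)
            leaf_hits[b] = lidx
            cnt = tree.leaf_count[lidx]
            ok = cnt > 0
            inv = np.where(ok, 1.0 / np.maximum(cnt, 1), 0.0)
            num += tree.leaf_sum_wz[lidx] * inv
            den += tree.leaf_sum_w[lidx] * inv
            contributing += ok
        if (contributing == 0).any():
            raise ValueError("no tree has neighbors for some query points")
        if (den <= 0).any():
            raise ValueError(
                "all neighbors of some query points are censored; consider a "
                "larger min_node_size or a smaller restriction time L"
            )
        mu = num / den
        if not return_psi:
            return mu
        # per-tree leaf averages of psi = w*(zL - mu_hat(x)); NaN if empty
        psi = np.full((len(self.trees), nq), np.nan)
        for b, tree in enumerate(self.trees):
            lidx = leaf_hits[b]
            cnt = tree.leaf_count[lidx]
            ok = cnt > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = (tree.leaf_sum_wz[lidx] - mu * tree.leaf_sum_w[lidx]) / cnt
            psi[b, ok] = vals[ok]
        return mu, psi


def fit_forest(rdata: RestrictedDataset, config: ForestConfig) -> SurvivalForest:
    """Fit the honest survival forest.

    ``G = B / group_size`` half-samples of size ``⌊n/2⌋`` are drawn
    without replacement; each group grows ``group_size`` trees from its
    half-sample.  Per-tree generators are spawned from the master seed by
    fixed jumps, so the build is order-independent.
    """
    n = rdata.n
    cfg = config.resolve(n, rdata.base.p)
    if n < 4 * config.min_node_size:
        raise ValueError(f"need n >= {4 * config.min_node_size}, got {n}")
    G = config.num_trees // config.group_size
    trees: list[HonestTree] = []
    for g in range(G):
        g_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=(config.seed, 2 * g))
        )
        half = g_rng.choice(n, size=n // 2, replace=False)
        for j in range(config.group_size):
            t_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=(config.seed, 2 * g + 1, j))
            )
            trees.append(build_tree(rdata, half, cfg, t_rng, group_id=g))
    cens = fit_cox_censoring(rdata.base)
    w_full = compute_ipcw(rdata, cens, floor=config.weight_floor)
    forest = SurvivalForest(
        trees=trees,
        config=config,
        resolved=cfg,
        rdata=rdata,
        censoring_model=cens,
        weights=w_full,
    )
    _attach_leaf_aggregates(forest)
    return forest


def _attach_leaf_aggregates(forest: SurvivalForest) -> None:
    w = forest.weights.w
    wz = w * forest.rdata.ZL
    for tree in forest.trees:
        sw = np.zeros(tree.n_nodes)
        swz = np.zeros(tree.n_nodes)
        leaves = np.flatnonzero(tree.feature < 0)
        for node in leaves:
            mem = tree.leaf_members(node)
            if mem.size:
                sw[node] = w[mem].sum()
                swz[node] = wz[mem].sum()
        tree.leaf_sum_w = sw
        tree.leaf_sum_wz = swz


@dataclass(frozen=True)
class ForestWeights:
    alpha: np.ndarray


def forest_weights(forest: SurvivalForest, x: np.ndarray) -> ForestWeights:
    """Data-adaptive kernel α_i(x): normalized leaf co-membership rates.

    ``α_i(x) = (1/B̃) Σ_b 1{X_i ∈ L_b(x)} / |L_b(x)|`` with ``B̃`` the
    number of trees whose leaf at ``x`` is nonempty; the weights sum to 1.
    """
    x = np.asarray(x, float).reshape(1, -1)
    alpha = np.zeros(forest.rdata.n)
    contributing = 0
    for tree in forest.trees:
        node = int(tree.leaf_for(x)[0])
        mem = tree.leaf_members(node)
        if mem.size:
            alpha[mem] += 1.0 / mem.size
            contributing += 1
    if contributing == 0:
        raise ValueError("no neighbors: every tree has an empty leaf at x")
    return ForestWeights(alpha=alpha / contributing)


def predict_rmst(forest: SurvivalForest, x: np.ndarray) -> float:
    """Closed-form solution of the locally weighted estimating equation."""
    return float(forest.predict(np.asarray(x, float).reshape(1, -1))[0])
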