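"""Honest forest: split criterion against exhaustive enumeration, honesty
and balance invariants, forest-weight algebra and the double-sum oracle."""

import math

import numpy as np
import pytest

from srforest import (
    ForestConfig,
    SimulationConfig,
    beta_min,
    fit_forest,
    forest_weights,
    generate,
    predict_rmst,
    restrict,
)
from srforest.forest import best_split, leaf_solution, pseudo_outcomes


# ---------------------------------------------------------------- beta_min
def test_beta_min_symmetric_case_is_half():
    assert beta_min(0.5, 1.0) == pytest.approx(0.5, abs=1e-12)


def test_beta_min_omega_point2():
    expected = 1 - 1 / (1 + math.log(5) / math.log(1.25))
    assert beta_min(0.2, 1.0) == pytest.approx(expected)
    assert beta_min(0.2, 1.0) == pytest.approx(0.8782, abs=5e-4)


def test_beta_min_increases_as_pi_decreases():
    vals = [beta_min(0.2, pi) for pi in (1.0, 0.5, 0.2, 0.1)]
    assert all(a < b for a, b in zip(vals, vals[1:]))
    with pytest.raises(ValueError):
        beta_min(0.7, 1.0)
    with pytest.raises(ValueError):
        beta_min(0.2, 0.0)


# ------------------------------------------------------- node-level pieces
def test_leaf_solution_examples(rng):
    z = np.array([2.0, 5.0])
    assert leaf_solution(np.array([1.0, 1.0]), z) == 3.5
    assert leaf_solution(np.array([1.0, 0.0]), z) == 2.0
    w = rng.uniform(0.1, 2.0, 10)
    zz = rng.uniform(0, 5, 10)
    assert leaf_solution(w, zz) == pytest.approx(np.dot(w, zz) / w.sum())
    with pytest.raises(ZeroDivisionError):
        leaf_solution(np.zeros(2), z)


def test_pseudo_outcomes_hand_case():
    w = np.array([2.0, 1.0])
    z = np.array([4.0, 1.0])
    mu = leaf_solution(w, z)
    assert mu == 3.0
    rho = pseudo_outcomes(w, z, mu)
    np.testing.assert_allclose(rho, [4.0 / 3.0, -4.0 / 3.0])


def test_pseudo_outcomes_sum_to_zero(rng):
    w = rng.uniform(0, 2, 30)
    z = rng.uniform(0, 5, 30)
    rho = pseudo_outcomes(w, z, leaf_solution(w, z))
    assert abs(rho.sum()) < 1e-10
    # unit weights reduce to centered outcomes
    rho1 = pseudo_outcomes(np.ones(30), z, z.mean())
    np.testing.assert_allclose(rho1, z - z.mean())


def _brute_force_split(X, rho, min_child):
    best = None
    for f in range(X.shape[1]):
        for thr in np.unique(X[:, f]):
            left = X[:, f] <= thr
            nl, nr = left.sum(), (~left).sum()
            if nl < min_child or nr < min_child or nr == 0:
                continue
            crit = rho[left].sum() ** 2 / nl + rho[~left].sum() ** 2 / nr
            if best is None or crit > best[0] + 1e-12:
                best = (crit, f)
    return best


def test_best_split_perfectly_separated():
    X = np.array([[0.1], [0.2], [0.8], [0.9]])
    rho = np.array([1.0, 1.0, -1.0, -1.0])
    f, thr, crit = best_split(X, rho, np.array([0]), min_child=1)
    assert f == 0 and 0.2 < thr < 0.8
    assert crit == pytest.approx(4.0)


def test_best_split_none_when_rho_zero():
    X = np.linspace(0, 1, 8).reshape(-1, 1)
    assert best_split(X, np.zeros(8), np.array([0]), min_child=1) is None


def test_best_split_matches_exhaustive_enumeration(rng):
    """Chosen criterion beats every admissible (feature, threshold) pair."""
    for trial in range(20):
        m = int(rng.integers(6, 50))
        X = rng.uniform(-1, 1, (m, 3))
        rho = rng.normal(size=m)
        rho -= rho.mean()
        got = best_split(X, rho, np.arange(3), min_child=2)
        expected = _brute_force_split(X, rho, min_child=2)
        if got is None:
            assert expected is None or expected[0] <= 1e-12
            continue
        assert got[2] == pytest.approx(expected[0], rel=1e-9)


# ------------------------------------------------------- forest structure
def test_honesty_and_min_node_size(small_forest):
    cfg = small_forest.config
    for tree in small_forest.trees:
        J = set(tree.structure_indices.tolist())
        I = set(tree.estimation_indices.tolist())
        assert not (J & I)
        # every estimation point lands in exactly one leaf
        members = np.sort(tree.members)
        np.testing.assert_array_equal(members, np.sort(tree.estimation_indices))


def test_split_balance_omega(small_forest):
    """Each split leaves >= omega fraction of structure points per child."""
    omega = small_forest.config.omega
    mns = small_forest.config.min_node_size
    X = small_forest.rdata.X
    for tree in small_forest.trees:
        nodes = tree.leaf_for(X[tree.structure_indices])
        # reconstruct per-node structure counts by descending the tree
        counts = np.zeros(tree.n_nodes, dtype=int)
        idx = np.zeros(len(tree.structure_indices), dtype=int)
        Xs = X[tree.structure_indices]
        counts[0] = len(idx)
        frontier = [0]
        assign = {0: np.arange(len(idx))}
        while frontier:
            node = frontier.pop()
            rows = assign.pop(node)
            f = tree.feature[node]
            if f < 0:
                assert len(rows) >= mns
                continue
            go = Xs[rows, f] <= tree.threshold[node]
            ln, rn = tree.left[node], tree.right[node]
            for child, sub in ((ln, rows[go]), (rn, rows[~go])):
                assert len(sub) >= max(mns, math.ceil(omega * len(rows)))
                assign[child] = sub
                frontier.append(child)


def test_forest_grouping_b10_l5(model1_restricted):
    cfg = ForestConfig(num_trees=10, group_size=5, seed=1, validate_exponent=False)
    forest = fit_forest(model1_restricted, cfg)
    assert forest.num_groups == 2
    gids = [t.group_id for t in forest.trees]
    assert gids == [0] * 5 + [1] * 5
    # trees in one group share the half-sample universe
    h0 = set(np.concatenate([forest.trees[i].structure_indices for i in range(5)]))
    h1 = set(np.concatenate([forest.trees[i].structure_indices for i in range(5, 10)]))
    assert h0 != h1


def test_group_size_must_divide_num_trees():
    with pytest.raises(ValueError, match="divisible"):
        ForestConfig(num_trees=10, group_size=3)


def test_seed_determinism(model1_restricted):
    cfg = ForestConfig(num_trees=8, seed=11, validate_exponent=False)
    f1 = fit_forest(model1_restricted, cfg)
    f2 = fit_forest(model1_restricted, cfg)
    Xq = model1_restricted.X[:50]
    np.testing.assert_array_equal(f1.predict(Xq), f2.predict(Xq))
    f3 = fit_forest(model1_restricted, ForestConfig(num_trees=8, seed=12,
                                                    validate_exponent=False))
    assert not np.array_equal(f1.predict(Xq), f3.predict(Xq))


# ------------------------------------------------------------- prediction
def test_forest_weights_are_distribution(small_forest, rng):
    for _ in range(5):
        x = rng.uniform(-1, 1, small_forest.rdata.base.p)
        alpha = forest_weights(small_forest, x).alpha
        assert alpha.sum() == pytest.approx(1.0)
        assert (alpha >= 0).all()
        # nonzero only on estimation-sample members
        est = np.zeros(small_forest.rdata.n, dtype=bool)
        for t in small_forest.trees:
            est[t.estimation_indices] = True
        assert not alpha[~est].any()


def test_single_tree_leaf_weights(model1_restricted):
    forest = fit_forest(
        model1_restricted,
        ForestConfig(num_trees=2, seed=5, validate_exponent=False),
    )
    tree = forest.trees[0]
    x = model1_restricted.X[0]
    node = int(tree.leaf_for(x.reshape(1, -1))[0])
    mem = tree.leaf_members(node)
    single = forest_weights(
        type(forest)(
            trees=[tree], config=forest.config, resolved=forest.resolved,
            rdata=forest.rdata, censoring_model=forest.censoring_model,
            weights=forest.weights,
        ),
        x,
    ).alpha
    np.testing.assert_allclose(single[mem], 1.0 / mem.size)


def test_prediction_equals_double_sum_oracle(small_forest, rng):
    """μ̂ᴸ(x) equals Σαŵz / Σαŵ computed via explicit forest weights."""
    w = small_forest.weights.w
    zL = small_forest.rdata.ZL
    for _ in range(10):
        x = rng.uniform(-1, 1, small_forest.rdata.base.p)
        alpha = forest_weights(small_forest, x).alpha
        oracle = np.sum(alpha * w * zL) / np.sum(alpha * w)
        assert predict_rmst(small_forest, x) == pytest.approx(oracle, rel=1e-10)


def test_predictions_within_bounds(small_forest):
    Xq = small_forest.rdata.X[:200]
    mu = small_forest.predict(Xq)
    assert (mu >= 0).all() and (mu <= small_forest.L).all()


def test_homogeneous_data_predictions_flat(rng):
    """No covariate effect: predictions vary within Monte-Carlo noise."""
    from srforest import SurvivalDataset

    n = 1500
    X = rng.uniform(-1, 1, (n, 2))
    T = 5.0 + rng.normal(0, 0.2, n)
    C = rng.exponential(1 / 0.08, n)
    data = SurvivalDataset(X, np.minimum(T, C), (T <= C))
    forest = fit_forest(
        restrict(data, 5.3),
        ForestConfig(num_trees=100, seed=3, validate_exponent=False),
    )
    grid = rng.uniform(-1, 1, (40, 2))
    mu = forest.predict(grid)
    # spread across x should stay near the per-point noise level
    assert mu.std() < 3 * 0.2 / np.sqrt(forest.resolved.s / 10)


def test_subsample_exponent_validation_warns():
    cfg = ForestConfig(num_trees=4, subsample_exponent=0.6)
    with pytest.warns(UserWarning, match="beta_min"):
        cfg.resolve(n=2000, p=5)
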