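"""Forest persistence: a self-describing, versioned JSON archive.

The archive stores the hyperparameters, the training sample (needed for
forest weights and estimating-function evaluations), the full-data
censoring model and every tree's structure, leaf membership and leaf
aggregates.  ``load_forest(save_forest(f)) `` reproduces predictions and
confidence intervals exactly.
"""

from __future__ import annotations

import json

import numpy as np

from .cox import CoxFit
from .data import RestrictedDataset, SurvivalDataset
from .forest import ForestConfig, HonestTree, SurvivalForest
from .ipcw import CensoringModel, IpcwWeights

__all__ = ["save_forest", "load_forest", "FORMAT_VERSION"]

FORMAT_VERSION = 1


def _arr(a, dtype=float):
    return np.asarray(a, dtype=dtype)


def save_forest(forest: SurvivalForest, path) -> None:
    cfg = forest.config
    d = forest.rdata
    payload = {
        "format": "srforest-archive",
        "version": FORMAT_VERSION,
        "config": {
            "num_trees": cfg.num_trees,
            "subsample_exponent": cfg.subsample_exponent,
            "subsample_size": cfg.subsample_size,
            "honesty_fraction": cfg.honesty_fraction,
            "min_node_size": cfg.min_node_size,
            "mtry": cfg.mtry,
            "omega": cfg.omega,
            "split_prob_floor": cfg.split_prob_floor,
            "group_size": cfg.group_size,
            "seed": cfg.seed,
            "weight_floor": cfg.weight_floor,
        },
        "L": d.L,
        "data": {
            "X": d.base.X.tolist(),
            "Z": d.base.Z.tolist(),
            "delta": d.base.delta.tolist(),
            "names": list(d.base.covariate_names),
        },
        "censoring": {
            "beta": forest.censoring_model.beta_C.tolist(),
            "times": forest.censoring_model.baseline_times.tolist(),
            "cumhaz": forest.censoring_model.baseline_cumhaz.tolist(),
            "degenerate": forest.censoring_model.degenerate,
        },
        "weights": {
            "w": forest.weights.w.tolist(),
            "floor_used": forest.weights.floor_used.astype(int).tolist(),
        },
        "trees": [
            {
                "feature": t.feature.tolist(),
                "threshold": t.threshold.tolist(),
                "left": t.left.tolist(),
                "right": t.right.tolist(),
                "leaf_start": t.leaf_start.tolist(),
                "leaf_count": t.leaf_count.tolist(),
                "members": t.members.tolist(),
                "structure": t.structure_indices.tolist(),
                "estimation": t.estimation_indices.tolist(),
                "group_id": t.group_id,
                "leaf_sum_w": t.leaf_sum_w.tolist(),
                "leaf_sum_wz": t.leaf_sum_wz.tolist(),
            }
            for t in forest.trees
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_forest(path) -> SurvivalForest:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "srforest-archive":
        raise ValueError(f"{path} is not a forest archive")
    if payload["version"] > FORMAT_VERSION:
        raise ValueError(f"archive version {payload['version']} is newer than supported")
    cfg = ForestConfig(**payload["config"])
    dd = payload["data"]
    base = SurvivalDataset(
        _arr(dd["X"]), _arr(dd["Z"]), _arr(dd["delta"], int), tuple(dd["names"])
    )
    from .data import restrict

    rdata = restrict(base, payload["L"])
    cz = payload["censoring"]
    cens = CensoringModel(
        fit=CoxFit(
            beta=_arr(cz["beta"]),
            baseline_times=_arr(cz["times"]),
            baseline_cumhaz=_arr(cz["cumhaz"]),
            iterations=0,
            converged=True,
            log_likelihood=float("nan"),
            degenerate=cz["degenerate"],
        )
    )
    weights = IpcwWeights(
        w=_arr(payload["weights"]["w"]),
        floor_used=_arr(payload["weights"]["floor_used"], int).astype(bool),
    )
    trees = []
    for td in payload["trees"]:
        trees.append(
            HonestTree(
                feature=_arr(td["feature"], np.int32),
                threshold=_arr(td["threshold"]),
                left=_arr(td["left"], np.int32),
                right=_arr(td["right"], np.int32),
                leaf_start=_arr(td["leaf_start"], np.int32),
                leaf_count=_arr(td["leaf_count"], np.int32),
                members=_arr(td["members"], np.int64),
                structure_indices=_arr(td["structure"], np.int64),
                estimation_indices=_arr(td["estimation"], np.int64),
                group_id=int(td["group_id"]),
                leaf_sum_w=_arr(td["leaf_sum_w"]),
                leaf_sum_wz=_arr(td["leaf_sum_wz"]),
            )
        )
    import dataclasses

    quiet = dataclasses.replace(cfg, validate_exponent=False)
    return SurvivalForest(
        trees=trees,
        config=cfg,
        resolved=quiet.resolve(rdata.n, rdata.base.p),
        rdata=rdata,
        censoring_model=cens,
        weights=weights,
    )
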