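"""Pool-based active learning with evidential-uncertainty acquisition.

The loop mirrors the standard uncertainty-driven design: train on a seed
set, score the candidate pool, move the N highest-uncertainty (or N random)
candidates into the training set, label them through a pluggable oracle,
retrain from scratch, and evaluate on a fixed held-out test set; repeat for
a set number of iterations and replicate over independent runs.  Within a
run the EDL and random arms are paired: they share the initial split, the
initial model, and the per-iteration model seeds, so per-iteration
comparisons across arms isolate the acquisition strategy.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import datasets as ds
from .evidential import EvidentialRegressor, desk_scale_model_params
from .shift import fcd_between_sets
from .stats import r_squared, rmse

__all__ = [
    "ALState",
    "ALConfig",
    "ALData",
    "select_by_uncertainty",
    "select_random",
    "run_iteration",
    "run_experiment",
    "PRESETS",
]

logger = logging.getLogger(__name__)

PRESETS = ("within_somas", "somas_to_pubchem", "cho_to_pubchem",
           "random_subset_to_pubchem")


@dataclass
class ALState:
    """Disjoint train/pool/test id sets plus the iteration counter."""

    train_ids: list
    pool_ids: list
    test_ids: list
    iteration: int = 0
    model: Optional[object] = None

    def check(self) -> None:
        tr, po, te = set(self.train_ids), set(self.pool_ids), set(self.test_ids)
        if tr & po or tr & te or po & te:
            raise ValueError("train/pool/test id sets are not disjoint")
        if len(tr) != len(self.train_ids) or len(po) != len(self.pool_ids):
            raise ValueError("duplicate ids within a set")


@dataclass
class ALConfig:
    """Loop configuration: batch size N, iteration and run counts, strategy,
    uncertainty mode, base seed and model parameters."""

    batch_size: int = 25
    n_iterations: int = 10
    n_runs: int = 10
    strategy: str = "both"
    uncertainty_mode: str = "aleatoric"
    base_seed: int = 0
    model_params: dict = field(default_factory=desk_scale_model_params)
    compute_fcd: bool = True


@dataclass
class ALData:
    """Feature lookup (indexed by id) plus the labels known so far."""

    features: pd.DataFrame       # index: id, columns: f_0..f_{d-1}
    labels: dict                 # id -> target

    @classmethod
    def from_frames(cls, *frames: pd.DataFrame) -> "ALData":
        combined = pd.concat(frames, axis=0)
        if combined["id"].duplicated().any():
            raise ValueError("duplicate ids across datasets")
        fcols = [c for c in combined.columns if c.startswith("f_")]
        feats = combined.set_index("id")[fcols]
        if "target" in combined.columns:
            labeled = combined[combined["target"].notna()]
            labels = dict(zip(labeled["id"], labeled["target"].astype(float)))
        else:
            labels = {}
        return cls(features=feats, labels=labels)

    def X(self, ids) -> np.ndarray:
        return self.features.loc[list(ids)].to_numpy(dtype=float)

    def y(self, ids) -> np.ndarray:
        return np.asarray([self.labels[i] for i in ids], dtype=float)


def select_by_uncertainty(pool_predictions, N: int):
    """Ids of the N most uncertain candidates (ties broken by ascending id)."""
    preds = list(pool_predictions)
    if N > len(preds):
        raise ValueError(f"requested {N} from pool of {len(preds)}")
    if any(not np.isfinite(u) for _, u in preds):
        raise ValueError("non-finite uncertainty values")
    ranked = sorted(preds, key=lambda t: (-t[1], t[0]))
    return [i for i, _ in ranked[:N]]


def select_random(pool_ids, N: int, seed: int):
    """Uniform sample of N ids without replacement, deterministic in seed."""
    ids = sorted(pool_ids)
    if N > len(ids):
        raise ValueError(f"requested {N} from pool of {len(ids)}")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(ids), size=N, replace=False)
    return [ids[k] for k in sorted(picked)]


def _fit_model(data: ALData, train_ids, model_params: dict, seed: int):
    model = EvidentialRegressor(**model_params, seed=seed)
    return model.fit(data.X(train_ids), data.y(train_ids))


def _evaluate(model, data: ALData, test_ids):
    pred = model.predict(data.X(test_ids))
    y = data.y(test_ids)
    return rmse(y, pred), r_squared(y, pred)


def run_iteration(state: ALState, cfg: ALConfig, oracle: Callable[[str], float],
                  data: ALData, strategy: Optional[str] = None,
                  model_seed: Optional[int] = None,
                  select_seed: Optional[int] = None, run: int = 0):
    """One acquisition step: select, label, retrain, evaluate.

    The oracle is called exactly once per newly selected id, before any
    state mutation, so an oracle failure leaves the state untouched.
    Returns the new state and the iteration record (a plain dict).
    """
    state.check()
    if not state.pool_ids:
        raise ValueError("pool is empty")
    strategy = strategy or cfg.strategy
    n_take = min(cfg.batch_size, len(state.pool_ids))

    if strategy == "edl":
        if state.model is None:
            raise ValueError("EDL strategy requires a fitted model in the state")
        unc = state.model.predict_uncertainty(data.X(state.pool_ids),
                                              mode=cfg.uncertainty_mode)
        selected = select_by_uncertainty(zip(state.pool_ids, unc), n_take)
    elif strategy == "random":
        if select_seed is None:
            select_seed = cfg.base_seed
        selected = select_random(state.pool_ids, n_take, select_seed)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    new_labels = {i: oracle(i) for i in selected}  # may raise: state untouched

    sel = set(selected)
    new_state = ALState(
        train_ids=list(state.train_ids) + list(selected),
        pool_ids=[i for i in state.pool_ids if i not in sel],
        test_ids=list(state.test_ids),
        iteration=state.iteration + 1,
    )
    new_state.check()
    assert len(new_state.train_ids) + len(new_state.pool_ids) == \
        len(state.train_ids) + len(state.pool_ids)
    data.labels.update(new_labels)

    if model_seed is None:
        model_seed = cfg.base_seed
    new_state.model = _fit_model(data, new_state.train_ids, cfg.model_params,
                                 model_seed)
    test_rmse, test_r2 = _evaluate(new_state.model, data, new_state.test_ids)
    record = {
        "run": run, "iteration": new_state.iteration, "strategy": strategy,
        "train_size": len(new_state.train_ids),
        "rmse": test_rmse, "r2": test_r2,
        "fcd_train_pool": (
            fcd_between_sets(data.X(new_state.train_ids), data.X(new_state.pool_ids))
            if cfg.compute_fcd and new_state.pool_ids else np.nan),
    }
    logger.info("run=%d iter=%d strategy=%s train=%d rmse=%.4f",
                run, new_state.iteration, strategy, record["train_size"], test_rmse)
    return new_state, record, selected


def _seed_for(base: int, *parts: int) -> int:
    return int(np.random.SeedSequence([base, *parts]).generate_state(1)[0] % (2 ** 31))


def _assemble_preset(preset: str, shift_cfg: ds.ShiftConfig, run_seed: int):
    """Initial (train, pool, test) datasets for one run of a preset."""
    in_dist, ood_pool, ood_test = ds.generate_bundle(shift_cfg)
    if preset == "within_somas":
        seed_set, test_set, pool_set = ds.split_in_distribution(
            in_dist, 0.09, 0.09, seed=run_seed)
        return seed_set, pool_set, test_set
    if preset == "somas_to_pubchem":
        return in_dist, ood_pool, ood_test
    if preset == "cho_to_pubchem":
        seed_set = ds.biased_subset(in_dist, "palette", seed=run_seed)
        return seed_set, ood_pool, ood_test
    if preset == "random_subset_to_pubchem":
        n_cho = len(ds.biased_subset(in_dist, "palette", seed=run_seed))
        seed_set = ds.biased_subset(in_dist, "random", size=n_cho, seed=run_seed)
        return seed_set, ood_pool, ood_test
    raise ValueError(f"unknown preset {preset!r}; choose one of {PRESETS}")


def run_experiment(preset: str, cfg: ALConfig, shift_cfg: ds.ShiftConfig,
                   oracle: Optional[Callable[[str], float]] = None):
    """Replicated EDL-vs-random experiment for one study design.

    Returns (iterations, selections) DataFrames.  Run r derives all of its
    randomness from ``base_seed`` and r; both arms of a run share the
    initial split, initial model and per-iteration model seeds (paired
    design).  By default the generator's own targets act as the labeling
    oracle; an external oracle can be injected.
    """
    strategies = ["edl", "random"] if cfg.strategy == "both" else [cfg.strategy]
    iter_rows, sel_rows = [], []

    for r in range(cfg.n_runs):
        run_seed = _seed_for(cfg.base_seed, r)
        seed_set, pool_set, test_set = _assemble_preset(preset, shift_cfg, run_seed)
        data0 = ALData.from_frames(seed_set, pool_set, test_set)
        the_oracle = oracle if oracle is not None else (lambda i: data0.labels[i])

        init_state = ALState(
            train_ids=list(seed_set["id"]),
            pool_ids=list(pool_set["id"]),
            test_ids=list(test_set["id"]),
        )
        init_state.check()
        init_state.model = _fit_model(data0, init_state.train_ids,
                                      cfg.model_params, _seed_for(cfg.base_seed, r, 0))
        rmse0, r20 = _evaluate(init_state.model, data0, init_state.test_ids)
        fcd0 = (fcd_between_sets(data0.X(init_state.train_ids),
                                 data0.X(init_state.pool_ids))
                if cfg.compute_fcd else np.nan)

        for strategy in strategies:
            iter_rows.append({
                "run": r, "iteration": 0, "strategy": strategy,
                "train_size": len(init_state.train_ids),
                "rmse": rmse0, "r2": r20, "fcd_train_pool": fcd0,
            })
            state = ALState(train_ids=list(init_state.train_ids),
                            pool_ids=list(init_state.pool_ids),
                            test_ids=list(init_state.test_ids),
                            model=init_state.model)
            data = ALData(features=data0.features, labels=dict(data0.labels))
            for it in range(1, cfg.n_iterations + 1):
                if not state.pool_ids:
                    logger.info("run=%d strategy=%s: pool exhausted at iter %d",
                                r, strategy, it)
                    break
                state, record, selected = run_iteration(
                    state, cfg, the_oracle, data, strategy=strategy,
                    model_seed=_seed_for(cfg.base_seed, r, it),
                    select_seed=_seed_for(cfg.base_seed, r, it, 7), run=r)
                iter_rows.append(record)
                for i in selected:
                    sel_rows.append({"run": r, "iteration": it,
                                     "strategy": strategy, "id": i,
                                     "target": data.labels[i]})

    iterations = pd.DataFrame(iter_rows)
    selections = pd.DataFrame(sel_rows, columns=["run", "iteration", "strategy",
                                                 "id", "target"])
    return iterations, selections
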