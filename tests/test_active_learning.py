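import dataclasses

import numpy as np
import pandas as pd
import pytest

from edal.active_learning import (
    ALConfig, ALData, ALState, run_experiment, run_iteration,
    select_by_uncertainty, select_random,
)
from edal.datasets import ShiftConfig, biased_subset, generate_bundle


class TestSelectByUncertainty:
    def test_top_n(self):
        preds = [("a", 0.1), ("b", 0.9), ("c", 0.5)]
        assert set(select_by_uncertainty(preds, 2)) == {"b", "c"}

    def test_whole_pool(self):
        preds = [("a", 0.1), ("b", 0.9)]
        assert set(select_by_uncertainty(preds, 2)) == {"a", "b"}

    def test_tie_broken_by_ascending_id(self):
        preds = [("b", 0.5), ("a", 0.5), ("c", 0.1)]
        assert select_by_uncertainty(preds, 1) == ["a"]

    def test_selected_dominate_unselected(self):
        rng = np.random.default_rng(0)
        preds = [(f"m{i}", float(u)) for i, u in enumerate(rng.random(50))]
        chosen = select_by_uncertainty(preds, 12)
        chosen_u = {i: u for i, u in preds if i in set(chosen)}
        rest_u = [u for i, u in preds if i not in set(chosen)]
        assert min(chosen_u.values()) >= max(rest_u)

    def test_oversize_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            select_by_uncertainty([("a", 1.0)], 2)
        with pytest.raises(ValueError):
            select_by_uncertainty([("a", np.nan)], 1)


class TestSelectRandom:
    def test_whole_pool(self):
        assert set(select_random(["a", "b", "c"], 3, seed=0)) == {"a", "b", "c"}

    def test_deterministic(self):
        ids = [f"m{i}" for i in range(30)]
        assert select_random(ids, 7, seed=42) == select_random(ids, 7, seed=42)

    def test_uniformity(self):
        ids = ["a", "b", "c", "d"]
        counts = {i: 0 for i in ids}
        for s in range(2000):
            counts[select_random(ids, 1, seed=s)[0]] += 1
        sigma = np.sqrt(0.25 * 0.75 / 2000)
        for i in ids:
            assert abs(counts[i] / 2000 - 0.25) < 3 * sigma

    def test_oversize_rejected(self):
        with pytest.raises(ValueError):
            select_random(["a"], 2, seed=0)


def _mock_setup(n_pool=40, n_train=10, n_test=10, seed=0):
    rng = np.random.default_rng(seed)
    n = n_pool + n_train + n_test
    ids = [f"m{i:03d}" for i in range(n)]
    feats = pd.DataFrame(rng.normal(size=(n, 3)),
                         columns=["f_0", "f_1", "f_2"], index=ids)
    labels = {i: float(rng.normal()) for i in ids}
    data = ALData(features=feats, labels=dict(labels))
    state = ALState(train_ids=ids[:n_train],
                    pool_ids=ids[n_train:n_train + n_pool],
                    test_ids=ids[n_train + n_pool:])
    return state, data, labels


class TestBookkeeping:
    """Conservation / disjointness / oracle-counting over randomized trials."""

    def test_randomized_trials(self, monkeypatch):
        import edal.active_learning as al_mod
        rng = np.random.default_rng(123)
        cfg = ALConfig(batch_size=5, model_params={})

        class FrozenModel:
            def predict(self, X):
                return np.zeros(len(X))

            def predict_uncertainty(self, X, mode="aleatoric"):
                return self._u

        frozen = FrozenModel()
        monkeypatch.setattr(al_mod, "_fit_model", lambda *a, **k: frozen)
        monkeypatch.setattr(al_mod, "_evaluate", lambda *a, **k: (1.0, 0.5))

        for trial in range(1000):
            n_pool = int(rng.integers(2, 25))
            batch = int(rng.integers(1, 8))
            state, data, labels = _mock_setup(n_pool=n_pool, seed=trial)
            frozen._u = rng.random(n_pool)
            state.model = frozen
            calls = []

            def oracle(i, labels=labels, calls=calls):
                calls.append(i)
                return labels[i]

            cfg_t = dataclasses.replace(cfg, batch_size=batch, compute_fcd=False)
            before = len(state.train_ids) + len(state.pool_ids)
            strategy = "edl" if trial % 2 == 0 else "random"
            new_state, record, selected = run_iteration(
                state, cfg_t, oracle, data, strategy=strategy, select_seed=trial)

            expect = min(batch, n_pool)
            assert len(selected) == expect
            assert len(calls) == expect          # one oracle call per id
            assert len(set(calls)) == expect     # no double labeling
            assert len(new_state.train_ids) + len(new_state.pool_ids) == before
            new_state.check()                    # disjointness

            if strategy == "edl":
                oracle_top = select_by_uncertainty(
                    list(zip(state.pool_ids, frozen._u)), expect)
                assert sorted(selected) == sorted(oracle_top)

    def test_oracle_failure_leaves_state_unchanged(self, monkeypatch):
        import edal.active_learning as al_mod
        monkeypatch.setattr(al_mod, "_fit_model",
                            lambda *a, **k: pytest.fail("must not retrain"))
        state, data, labels = _mock_setup(seed=1)
        train0, pool0 = list(state.train_ids), list(state.pool_ids)

        def bad_oracle(i):
            raise RuntimeError("labeler offline")

        cfg = ALConfig(batch_size=3, model_params={})
        with pytest.raises(RuntimeError):
            run_iteration(state, cfg, bad_oracle, data, strategy="random",
                          select_seed=0)
        assert state.train_ids == train0
        assert state.pool_ids == pool0

    def test_state_invariant_violations_detected(self):
        st = ALState(train_ids=["a"], pool_ids=["a", "b"], test_ids=["c"])
        with pytest.raises(ValueError):
            st.check()


class TestRunExperiment:
    def test_cardinality_and_pairing(self, tiny_shift_cfg, tiny_model_params):
        al = ALConfig(batch_size=10, n_iterations=1, n_runs=2, strategy="both",
                      base_seed=3, model_params=tiny_model_params,
                      compute_fcd=False)
        iters, sels = run_experiment("somas_to_pubchem", al, tiny_shift_cfg)
        # n_runs x (1 + n_iterations) x 2 strategies
        assert len(iters) == 2 * 2 * 2
        # paired arms share the initial record exactly
        it0 = iters[iters.iteration == 0]
        for r in (0, 1):
            vals = it0[it0.run == r]
            assert vals["rmse"].nunique() == 1
            assert vals["train_size"].nunique() == 1
        # selections: one row per acquired molecule
        assert len(sels) == 2 * 2 * 10
        assert sels["target"].notna().all()

    def test_train_size_strictly_increasing(self, tiny_shift_cfg, tiny_model_params):
        al = ALConfig(batch_size=5, n_iterations=3, n_runs=1, strategy="edl",
                      base_seed=1, model_params=tiny_model_params,
                      compute_fcd=False)
        iters, _ = run_experiment("somas_to_pubchem", al, tiny_shift_cfg)
        sizes = iters.sort_values("iteration")["train_size"].to_numpy()
        assert (np.diff(sizes) > 0).all()

    def test_within_somas_initial_sizes(self, tiny_model_params):
        cfg = ShiftConfig(n_in=200, n_pool=20, n_test=20, d=6, seed=7)
        al = ALConfig(batch_size=5, n_iterations=1, n_runs=1, strategy="random",
                      base_seed=0, model_params=tiny_model_params,
                      compute_fcd=False)
        iters, _ = run_experiment("within_somas", al, cfg)
        assert iters[iters.iteration == 0]["train_size"].iloc[0] == round(0.09 * 200)

    def test_cho_preset_uses_palette_records(self, tiny_model_params):
        cfg = ShiftConfig(n_in=300, n_pool=60, n_test=40, d=6, seed=7)
        in_dist, _, _ = generate_bundle(cfg)
        eligible = set(biased_subset(in_dist, "palette")["id"])
        al = ALConfig(batch_size=5, n_iterations=1, n_runs=1, strategy="random",
                      base_seed=0, model_params=tiny_model_params,
                      compute_fcd=False)
        iters, _ = run_experiment("cho_to_pubchem", al, cfg)
        assert iters[iters.iteration == 0]["train_size"].iloc[0] == len(eligible)

    def test_pool_exhaustion_stops_early(self, tiny_model_params):
        cfg = ShiftConfig(n_in=150, n_pool=12, n_test=30, d=6, seed=2)
        al = ALConfig(batch_size=10, n_iterations=5, n_runs=1, strategy="random",
                      base_seed=0, model_params=tiny_model_params,
                      compute_fcd=False)
        iters, _ = run_experiment("somas_to_pubchem", al, cfg)
        # pool of 12 at batch 10: two iterations (10 + 2), then stop
        assert iters["iteration"].max() == 2
        assert iters["train_size"].max() == 150 + 12

    def test_unknown_preset_rejected(self, tiny_shift_cfg):
        with pytest.raises(ValueError):
            run_experiment("bogus", ALConfig(), tiny_shift_cfg)
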