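import numpy as np
import pandas as pd
import pytest

from nichescreen.maxent_engine import ModelSettings, fit
from nichescreen.mc_screen import (EnsembleResult, ScreenConfig, ScreenData,
                                   SprintRecord, TallyTable, draw_subset,
                                   execute_run, run_ensemble, run_sprint,
                                   stability_sprint, subset_count, top_k,
                                   update_tally)
from nichescreen.model_metrics import permutation_importance

POOL6 = tuple(f"env{i + 1:02d}" for i in range(6))


def small_config(data, **kw):
    kw.setdefault("pool", tuple(data.presence.columns))
    kw.setdefault("k_per_run", 2)
    kw.setdefault("runs_per_sprint", 3)
    kw.setdefault("n_sprints", 2)
    kw.setdefault("top_k", 3)
    kw.setdefault("settings", ModelSettings(feature_classes="LQ"))
    return ScreenConfig(**kw)


class TestSubsetCount:
    def test_pool19_choose6(self):
        assert subset_count(19, 6) == 27_132

    def test_choose_all(self):
        assert subset_count(7, 7) == 1

    def test_pool19_choose2(self):
        assert subset_count(19, 2) == 171  # 19*18/2

    def test_k_exceeds_n(self):
        with pytest.raises(ValueError):
            subset_count(5, 6)


class TestDrawSubset:
    def test_full_pool(self):
        rng = np.random.default_rng(0)
        assert draw_subset(POOL6, 6, rng) == list(POOL6)

    def test_deterministic_from_stream_state(self):
        a = draw_subset(POOL6, 3, np.random.default_rng(42))
        b = draw_subset(POOL6, 3, np.random.default_rng(42))
        assert a == b

    def test_uniform_inclusion_frequency(self):
        """k=2 over a 19-variable pool: per-variable inclusion over 10,000
        draws should match 2/19 within 3 binomial sigma."""
        pool = tuple(f"v{i}" for i in range(19))
        rng = np.random.default_rng(1)
        counts = {v: 0 for v in pool}
        n_draws = 10_000
        for _ in range(n_draws):
            for v in draw_subset(pool, 2, rng):
                counts[v] += 1
        p = 2 / 19
        sigma = np.sqrt(n_draws * p * (1 - p))
        for v in pool:
            assert abs(counts[v] - n_draws * p) < 3 * sigma

    def test_distinct_members(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            s = draw_subset(POOL6, 4, rng)
            assert len(set(s)) == 4


class TestTally:
    def test_first_run_update(self):
        t = TallyTable(["bio01", "bio03", "bio07"])
        update_tally(t, {"bio03": 60.0, "bio07": 40.0})
        frame = t.to_frame().set_index("variable")
        assert frame.loc["bio03", "use_count"] == 1
        assert frame.loc["bio03", "cum_importance"] == 60.0
        assert frame.loc["bio01", "use_count"] == 0

    def test_running_average_hand_arithmetic(self):
        t = TallyTable(["bio01", "bio03", "bio07"])
        update_tally(t, {"bio03": 60.0, "bio07": 40.0})
        update_tally(t, {"bio03": 20.0, "bio01": 80.0})
        frame = t.to_frame().set_index("variable")
        assert frame.loc["bio03", "use_count"] == 2
        assert frame.loc["bio03", "cum_importance"] == 80.0
        assert frame.loc["bio03", "avg_importance"] == 40.0

    def test_conservation_sum_counts(self):
        rng = np.random.default_rng(5)
        t = TallyTable(POOL6)
        k, runs = 2, 37
        for _ in range(runs):
            sub = draw_subset(POOL6, k, rng)
            w = rng.random(k)
            update_tally(t, dict(zip(sub, 100 * w / w.sum())))
        assert t.use_count.sum() == k * runs

    def test_unknown_variable_rejected(self):
        t = TallyTable(POOL6)
        with pytest.raises(KeyError):
            update_tally(t, {"nope": 50.0})


class TestTopK:
    def _tally(self, avgs):
        t = TallyTable(list(avgs))
        for v, a in avgs.items():
            update_tally(t, {v: a})
        return t

    def test_tie_breaks_by_pool_order(self):
        t = self._tally({"a": 50.0, "b": 50.0, "c": 10.0})
        assert top_k(t, 2) == ["a", "b"]

    def test_full_ranking(self):
        t = self._tally({"a": 10.0, "b": 30.0, "c": 20.0})
        assert top_k(t, 3) == ["b", "c", "a"]

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(6)
        t = TallyTable(POOL6)
        for _ in range(40):
            sub = draw_subset(POOL6, 3, rng)
            w = rng.random(3)
            update_tally(t, dict(zip(sub, 100 * w / w.sum())))
        frame = t.to_frame()
        oracle = list(frame.sort_values("avg_importance", ascending=False,
                                        kind="stable").variable[:4])
        assert top_k(t, 4) == oracle

    def test_deferred_until_enough_used(self):
        t = self._tally({"a": 10.0})
        t2 = TallyTable(["a", "b", "c"])
        update_tally(t2, {"a": 100.0})
        assert top_k(t2, 2) is None


class TestExecuteRun:
    def test_singleton_subset_importance_100(self, small_data):
        data, _, _ = small_data
        out = execute_run(["env01"], data.presence, data.background,
                          ModelSettings(feature_classes="LQ"), run_seed=1)
        assert out == {"env01": 100.0}

    def test_identical_inputs_identical_output(self, small_data):
        data, _, _ = small_data
        args = (["env01", "env04"], data.presence, data.background,
                ModelSettings(feature_classes="LQ"))
        assert execute_run(*args, run_seed=9) == execute_run(*args, run_seed=9)

    def test_signal_beats_noise_in_most_runs(self):
        """With a strong single signal variable and an independent noise
        layer, the signal's importance should win in at least 90% of
        seeded runs."""
        from nichescreen.synthetic_data import SyntheticScenario, make_screen_data
        scenario = SyntheticScenario(
            grid_shape=(40, 40), n_layers=2, cross_correlation=None,
            true_variables=("env01",),
            true_coefficients={"linear": {"env01": 3.0}},
            n_presences=100, seed=21)
        data, _, _ = make_screen_data(scenario, n_background=500)
        wins = 0
        for s in range(50):
            out = execute_run(["env01", "env02"], data.presence, data.background,
                              ModelSettings(feature_classes="LQ"), run_seed=s)
            wins += out["env01"] > out["env02"]
        assert wins >= 45

    def test_importances_sum_to_100(self, small_data):
        data, _, _ = small_data
        out = execute_run(["env01", "env02", "env03"], data.presence,
                          data.background, ModelSettings(feature_classes="LQ"),
                          run_seed=2)
        assert sum(out.values()) == pytest.approx(100.0, abs=1e-6)

    def test_empty_subset_rejected(self, small_data):
        data, _, _ = small_data
        with pytest.raises(ValueError):
            execute_run([], data.presence, data.background, ModelSettings(), 0)


class TestRunSprintAndEnsemble:
    def test_sprint_count_accounting(self, small_data):
        data, _, _ = small_data
        cfg = small_config(data, runs_per_sprint=10, n_sprints=1)
        tally = TallyTable(cfg.pool)
        run_sprint(cfg, data, 1, tally)
        assert tally.use_count.sum() == 10 * cfg.k_per_run

    def test_sprint_end_model_uses_current_top_k(self, small_data):
        data, _, _ = small_data
        cfg = small_config(data, runs_per_sprint=6, n_sprints=1)
        tally = TallyTable(cfg.pool)
        record, model = run_sprint(cfg, data, 1, tally)
        if record.top_list is not None:
            assert model is not None
            assert model.variable_names == record.top_list
            assert record.model_aicc is not None

    def test_sprint_end_aicc_finite_across_seeds(self, small_data):
        data, _, _ = small_data
        for seed in range(5):
            cfg = small_config(data, runs_per_sprint=8, n_sprints=1,
                               master_seed=seed)
            tally = TallyTable(cfg.pool)
            record, _ = run_sprint(cfg, data, 1, tally)
            if record.top_list is not None:
                assert np.isfinite(record.model_aicc)

    def test_ensemble_total_runs_and_conservation(self, small_data):
        data, _, _ = small_data
        cfg = small_config(data, n_sprints=3)
        res = run_ensemble(cfg, data)
        assert res.total_runs == 3 * cfg.runs_per_sprint
        assert res.tally.use_count.sum() == cfg.k_per_run * res.total_runs

    def test_single_sprint_ensemble_equals_run_sprint(self, small_data):
        data, _, _ = small_data
        cfg = small_config(data, n_sprints=1, runs_per_sprint=5)
        res = run_ensemble(cfg, data)
        tally = TallyTable(cfg.pool)
        record, _ = run_sprint(cfg, data, 1, tally)
        assert res.records[0].subsets == record.subsets
        np.testing.assert_array_equal(res.tally.use_count, tally.use_count)
        np.testing.assert_allclose(res.tally.cum_importance, tally.cum_importance)

    def test_master_seed_reproducibility_and_workers(self, small_data):
        data, _, _ = small_data
        cfg = small_config(data, n_sprints=2, master_seed=17)
        r1 = run_ensemble(cfg, data, workers=1)
        r2 = run_ensemble(cfg, data, workers=2)
        pd.testing.assert_frame_equal(r1.sprint_log_frame(), r2.sprint_log_frame())
        np.testing.assert_allclose(r1.tally.cum_importance, r2.tally.cum_importance)

    def test_dry_run_draws_without_fitting(self, small_data):
        data, _, _ = small_data
        cfg = small_config(data, n_sprints=4)
        res = run_ensemble(cfg, dry_run=True)
        assert res.total_runs == 4 * cfg.runs_per_sprint
        assert res.tally.use_count.sum() == cfg.k_per_run * res.total_runs
        assert res.tally.cum_importance.sum() == 0.0

    def test_full_pool_reduction_matches_replicate_baseline(self, small_data):
        """With k_per_run = n every run is a full-pool model; the tally
        average must equal the mean of independently computed full-model
        permutation importances under the same per-run seeds."""
        data, _, _ = small_data
        pool = tuple(data.presence.columns)
        cfg = ScreenConfig(pool=pool, k_per_run=len(pool), runs_per_sprint=3,
                           n_sprints=1, top_k=3,
                           settings=ModelSettings(feature_classes="LQ"),
                           master_seed=5, sprint_models="none")
        res = run_ensemble(cfg, data)
        oracle = []
        for r in range(3):
            ss = np.random.SeedSequence([5, r])
            fit_seed, perm_seed = (int(s) for s in ss.generate_state(2) % (2 ** 31))
            model = fit(data.presence, data.background, cfg.settings,
                        seed=fit_seed)
            oracle.append(permutation_importance(model, data.presence,
                                                 data.background, seed=perm_seed))
        mean_imp = pd.concat(oracle, axis=1).mean(axis=1)
        for i, v in enumerate(pool):
            assert res.tally.avg_importance[i] == pytest.approx(mean_imp[v], abs=1e-9)

    def test_early_stopping_rule(self, small_data):
        data, _, _ = small_data
        cfg = small_config(data, n_sprints=8, runs_per_sprint=6,
                           stop_after_stable=2)
        res = run_ensemble(cfg, data)
        if res.stopped_early:
            assert len(res.records) < 8

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScreenConfig(pool=POOL6, k_per_run=7)
        with pytest.raises(ValueError):
            ScreenConfig(pool=POOL6, k_per_run=2, top_k=9)
        with pytest.raises(ValueError):
            ScreenConfig(pool=POOL6, k_per_run=2, n_sprints=5, checkpoints=(9,))


class TestStabilitySprint:
    def _records(self, tops):
        return [SprintRecord(i + 1, [], [], [], pd.DataFrame(), t)
                for i, t in enumerate(tops)]

    def test_stable_throughout(self):
        recs = self._records([["a", "b"]] * 5)
        assert stability_sprint(recs, "set") == 1

    def test_changes_in_final_sprint(self):
        recs = self._records([["a", "b"]] * 4 + [["a", "c"]])
        assert stability_sprint(recs, "set") is None

    def test_hand_built_log_set_vs_order(self):
        """Membership settles at sprint 7 but the rank order keeps swapping
        until sprint 9."""
        tops = ([["a", "b"], ["a", "c"]] * 3            # sprints 1-6 unstable
                + [["b", "a"], ["b", "a"], ["a", "b"], ["a", "b"]])
        recs = self._records(tops)
        assert stability_sprint(recs, "set") == 7
        assert stability_sprint(recs, "order") == 9

    def test_deferred_final_selection(self):
        recs = self._records([["a", "b"], None])
        assert stability_sprint(recs, "set") is None


class TestEnsembleOutputs:
    def test_sprint_log_frame_layout(self, small_data, tmp_path):
        data, _, _ = small_data
        cfg = small_config(data, n_sprints=2)
        res = run_ensemble(cfg, data)
        log = res.sprint_log_frame()
        assert list(log.sprint) == [1, 2]
        assert set(cfg.pool) <= set(log.columns)
        membership = log[list(cfg.pool)].to_numpy().sum(axis=1)
        assert all(m in (0, cfg.top_k) for m in membership)
        res.tally.to_csv(tmp_path / "tally.csv")
        assert (tmp_path / "tally.csv").exists()
        res.to_json(tmp_path / "summary.json")
        summary = res.summary()
        assert summary["total_runs"] == res.total_runs
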