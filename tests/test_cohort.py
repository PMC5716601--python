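"""Tests of the synthetic-cohort generator."""

import numpy as np
import pandas as pd
import pytest

from valuetasks.cohort import (
    CohortConfig,
    TRIAL_TABLE_COLUMNS,
    make_grid_design,
    sample_informative_pairs,
    sample_subject_params,
    simulate_cohort,
    simulate_task,
)
from valuetasks.value_models import get_spec


class TestGridDesign:
    def test_counts_and_sessions(self):
        d = make_grid_design(10.0)
        assert len(d) == 121
        assert d.groupby("session").size().tolist() == [40, 41, 40]
        # exact coverage of the grid, each combination once
        assert len(d.drop_duplicates(["gain", "donation"])) == 121
        assert len(make_grid_design(50.0)) == 9

    def test_seeded_order_reproducible(self):
        a = make_grid_design(10.0, np.random.default_rng(5))
        b = make_grid_design(10.0, np.random.default_rng(5))
        pd.testing.assert_frame_equal(a, b)

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError):
            make_grid_design(30.0)


class TestSubjectParams:
    def test_degenerate_population_is_constant(self):
        cfg = CohortConfig(value_pop={"alpha": (0.3228, 0.0), "delta": (0.405, 0.0)})
        rng = np.random.default_rng(0)
        draws = [sample_subject_params(cfg, rng) for _ in range(5)]
        alphas = {round(p["value"]["rating"]["alpha"], 6) for p in draws}
        assert alphas == {round(1 / (1 + np.exp(-0.3228)), 6)}

    def test_population_mean_matches_target(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(7)
        alphas = [
            sample_subject_params(cfg, rng)["value"]["rating"]["alpha"]
            for _ in range(1000)
        ]
        assert abs(np.mean(alphas) - 0.58) < 0.1

    def test_per_task_override_changes_location_only_for_that_param(self):
        cfg = CohortConfig(
            value_pop_loc_by_task={"delta": {"choice": np.log(1.1)}},
            value_pop={"alpha": (0.3228, 0.3), "delta": (np.log(2.0), 0.0)},
        )
        p = sample_subject_params(cfg, np.random.default_rng(3))
        assert p["value"]["choice"]["delta"] == pytest.approx(1.1)
        assert p["value"]["rating"]["delta"] == pytest.approx(2.0)
        # alpha stays a shared subject-level trait
        assert p["value"]["choice"]["alpha"] == p["value"]["force"]["alpha"]


class TestSimulation:
    def test_noiseless_chain_reproduces_scaled_value(self):
        cfg = CohortConfig()
        params = {
            "model": "ces",
            "value": {t: {"alpha": 0.5, "delta": 1.0} for t in ("rating", "force", "choice")},
            "temperature": 5.0,
            "rating": {"slope": 0.1, "intercept": 0.0, "noise_sd": 0.0},
            "force": {"slope": 0.8, "intercept": 0.0, "noise_sd": 0.0},
        }
        design = make_grid_design(10.0)
        out = simulate_task(params, "rating", design, cfg, np.random.default_rng(0))
        row = out[(out.gain_left == 50) & (out.donation_left == 50)]
        assert row["response"].iloc[0] == pytest.approx(5.0)

    def test_cold_temperature_always_picks_better_option(self):
        cfg = CohortConfig()
        params = {
            "model": "ces",
            "value": {t: {"alpha": 0.5, "delta": 1.0} for t in ("rating", "force", "choice")},
            "temperature": 1e-6,
            "rating": {"slope": 0.1, "intercept": 0.0, "noise_sd": 0.0},
            "force": {"slope": 0.8, "intercept": 0.0, "noise_sd": 0.0},
        }
        design = pd.DataFrame(
            {
                "gain_left": [80.0] * 20,
                "donation_left": [80.0] * 20,
                "gain_right": [10.0] * 20,
                "donation_right": [20.0] * 20,
            }
        )
        out = simulate_task(params, "choice", design, cfg, np.random.default_rng(0))
        assert (out["response"] == 1.0).all()

    def test_choice_frequency_monotone_in_value_difference(self, small_cohort):
        datasets, _ = small_cohort
        frames = [d.task("choice") for d in datasets]
        spec = get_spec("ces")
        props = []
        for d, df in zip(datasets, frames):
            vp = d.true_params["value"]["choice"]
            dv = spec.value(vp, df.gain_left, df.donation_left) - spec.value(
                vp, df.gain_right, df.donation_right
            )
            props.append(pd.DataFrame({"dv": dv, "y": df.response}))
        allp = pd.concat(props)
        binned = allp.groupby(pd.cut(allp.dv, [-100, -20, -5, 5, 20, 100]), observed=True)[
            "y"
        ].mean()
        assert binned.is_monotonic_increasing


class TestCohort:
    def test_shapes_counts_and_design_invariants(self, small_cohort):
        datasets, table = small_cohort
        assert len(datasets) == 3
        assert list(table.columns) == list(TRIAL_TABLE_COLUMNS)
        per_subject = table.groupby("subject").size()
        assert (per_subject == 121 + 121 + 200).all()
        for ds in datasets:
            for task in ("rating", "force"):
                tdf = ds.task(task)
                assert len(tdf.drop_duplicates(["gain_left", "donation_left"])) == 121
        # responses within bounds
        r = table[table.task == "rating"].response
        f = table[table.task == "force"].response
        assert r.between(0, 10).all() and f.between(10, 100).all()
        assert table[table.task == "choice"].response.isin([0.0, 1.0]).all()

    def test_choice_pairs_are_informative(self, small_cohort):
        _, table = small_cohort
        ch = table[table.task == "choice"]
        dg = ch.gain_left - ch.gain_right
        dd = ch.donation_left - ch.donation_right
        assert (dg != 0).all() and (dd != 0).all()
        assert (np.sign(dg) == -np.sign(dd)).all()

    def test_reproducible_from_master_seed(self, tmp_path):
        cfg = CohortConfig(n_subjects=1, seed=9)
        _, t1 = simulate_cohort(cfg, tmp_path / "a.csv")
        _, t2 = simulate_cohort(cfg, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
        pd.testing.assert_frame_equal(t1, t2)

    def test_force_production_averages_seventy_percent(self):
        # with scaling chosen so a*V + b averages 70 on the grid, mean
        # simulated force comes out near 70% of maximum
        cfg = CohortConfig(
            n_subjects=6,
            seed=1,
            value_pop={"alpha": (0.3228, 0.0), "delta": (np.log(1.5), 0.0)},
            slope_log_scale=0.0,
            force_intercept_scale=0.0,
        )
        spec = get_spec("ces")
        g = make_grid_design(10.0)
        vbar = float(
            np.mean(spec.value({"alpha": 0.58, "delta": 1.5}, g.gain, g.donation))
        )
        cfg.force_slope = 0.8
        cfg.force_intercept = 70.0 - 0.8 * vbar
        _, table = simulate_cohort(cfg)
        mean_force = table[table.task == "force"].response.mean()
        assert abs(mean_force - 70.0) < 2.0

    def test_informative_pair_sampler_has_no_repeats(self):
        rng = np.random.default_rng(2)
        pairs = sample_informative_pairs(300, rng, step=1.0)
        canon = {
            tuple(sorted([(r.gain_left, r.donation_left), (r.gain_right, r.donation_right)]))
            for r in pairs.itertuples()
        }
        assert len(canon) == 300
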