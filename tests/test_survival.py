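"""Lifetime construction, stage cleaning, the up-regulation feature and Cox."""

import numpy as np
import pandas as pd
import pytest

from topicsbm.survival import (clean_stage, cluster_survival_zscore,
                               compute_lifetime, cox_fit, five_year_survival,
                               upregulation_feature)


class TestLifetime:
    def test_dead_and_alive_rules(self):
        df = pd.DataFrame({
            "vital_status": ["Dead", "Alive"],
            "days_to_death": [400.0, np.nan],
            "days_to_last_follow_up": [np.nan, 900.0],
        })
        out = compute_lifetime(df)
        assert list(out["duration_days"]) == [400.0, 900.0]
        assert list(out["event"]) == [1, 0]

    def test_mixed_fixture_matches_manual_rule_application(self):
        df = pd.DataFrame({
            "vital_status": ["Dead", "Alive", "Dead", "Alive", "Dead",
                             "Alive", "Dead", "Alive", "Dead", "Alive"],
            "days_to_death": [100, np.nan, np.nan, np.nan, 50,
                              np.nan, -5, np.nan, 300, np.nan],
            "days_to_last_follow_up": [np.nan, 200, 999, np.nan, 1,
                                       0, 70, 800, 2, 60],
        })
        out = compute_lifetime(df)
        # manual application: rows 0, 1, 4, 7, 8, 9 retained
        assert list(out["duration_days"]) == [100, 200, 50, 800, 300, 60]
        assert list(out["event"]) == [1, 0, 1, 0, 1, 0]

    def test_unknown_status_rejected(self):
        df = pd.DataFrame({"vital_status": ["Unknown"],
                           "days_to_death": [1.0],
                           "days_to_last_follow_up": [1.0]})
        with pytest.raises(ValueError):
            compute_lifetime(df)


class TestCleanStage:
    @pytest.mark.parametrize("raw,expected", [
        ("stage ia", "i"),
        ("stage iiib", "iii"),
        ("Stage IV", "iv"),
        ("ii", "ii"),
        ("stage iic", "ii"),
    ])
    def test_substage_letters_stripped(self, raw, expected):
        assert clean_stage(raw) == expected

    @pytest.mark.parametrize("raw", ["nan", "not reported", None, float("nan"), ""])
    def test_missing_values_map_to_none(self, raw):
        assert clean_stage(raw) is None

    def test_unrecognized_label_warns(self):
        with pytest.warns(UserWarning):
            assert clean_stage("stage x") is None


class TestUpregulation:
    def _frame(self, values):
        return pd.DataFrame({"topic0": values})

    def test_interpolated_median_threshold(self):
        up = upregulation_feature(self._frame([0.1, 0.2, 0.3, 0.4]), 0)
        assert list(up) == [0, 0, 1, 1]

    def test_constant_column_all_zero(self):
        with pytest.warns(UserWarning):
            up = upregulation_feature(self._frame([0.3] * 5), 0)
        assert list(up) == [0] * 5

    def test_101_distinct_values_flag_exactly_50(self):
        rng = np.random.default_rng(0)
        values = rng.permutation(np.linspace(0.01, 0.99, 101))
        up = upregulation_feature(self._frame(values), 0)
        assert up.sum() == 50

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(size=37)
        base = upregulation_feature(self._frame(values), 0)
        squashed = upregulation_feature(self._frame(np.log1p(3 * values)), 0)
        assert list(base) == list(squashed)


def _exponential_cohort(n, hazard_ratio, seed, censor=0.0):
    rng = np.random.default_rng(seed)
    group = (np.arange(n) % 2).astype(float)
    hazard = 0.001 * hazard_ratio ** group
    times = rng.exponential(1.0 / hazard)
    event = np.ones(n, dtype=int)
    if censor > 0:
        cmax = np.quantile(times, 1 - censor) * 2
        c = rng.uniform(0, cmax, size=n)
        event = (times <= c).astype(int)
        times = np.minimum(times, c)
    clin = pd.DataFrame({"duration_days": times, "event": event})
    return clin, group


class TestCox:
    def test_recovers_hazard_ratio_two(self):
        clin, group = _exponential_cohort(2000, 2.0, seed=0)
        res = cox_fit(clin, group)
        assert 1.8 <= res.hazard_ratio <= 2.2
        assert res.p_value < 1e-6

    def test_null_covariate_centers_on_one(self):
        hits = 0
        for seed in range(20):
            clin, _ = _exponential_cohort(500, 1.0, seed=seed)
            rng = np.random.default_rng(1000 + seed)
            res = cox_fit(clin, rng.integers(0, 2, 500).astype(float))
            hits += abs(res.coef) < 0.2
        assert hits >= 18

    def test_bias_shrinks_with_sample_size(self):
        biases = {}
        for n in (250, 1000):
            coefs = [cox_fit(*_exponential_cohort(n, 2.0, seed=s)).coef
                     for s in range(10)]
            biases[n] = abs(np.mean(coefs) - np.log(2.0))
        assert biases[1000] <= biases[250] + 0.01

    def test_time_rescaling_leaves_coef_unchanged(self):
        clin, group = _exponential_cohort(400, 2.0, seed=3)
        res = cox_fit(clin, group)
        doubled = clin.assign(duration_days=clin["duration_days"] * 2)
        res2 = cox_fit(doubled, group)
        assert res2.coef == pytest.approx(res.coef, abs=1e-8)

    def test_degenerate_inputs_rejected(self):
        clin, group = _exponential_cohort(50, 2.0, seed=4)
        with pytest.raises(ValueError):
            cox_fit(clin, np.zeros(50))
        no_events = clin.assign(event=0)
        with pytest.raises(ValueError):
            cox_fit(no_events, group)


class TestFiveYear:
    def test_all_long_survivors(self):
        clin = pd.DataFrame({"duration_days": [2000.0, 3000.0],
                             "event": [0, 0]})
        assert five_year_survival(clin) == 1.0

    def test_half_and_half(self):
        clin = pd.DataFrame({"duration_days": [100.0] * 5 + [3000.0] * 5,
                             "event": [1] * 5 + [0] * 5})
        assert five_year_survival(clin) == 0.5

    def test_20_record_fixture_matches_manual_count(self):
        rng = np.random.default_rng(5)
        durations = rng.uniform(100, 4000, size=20)
        clin = pd.DataFrame({"duration_days": durations,
                             "event": rng.integers(0, 2, 20)})
        manual = sum(1 for d in durations if d >= 1825) / 20
        assert five_year_survival(clin) == pytest.approx(manual)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            five_year_survival(pd.DataFrame({"duration_days": [], "event": []}))


class TestClusterZscores:
    def _cohort(self, seed, n=200):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "duration_days": rng.exponential(2000, size=n),
            "event": np.ones(n, dtype=int),
        })

    def test_planted_low_survival_cluster_strongly_negative(self):
        clin = self._cohort(0)
        clin.loc[:49, "duration_days"] = 50.0  # early deaths
        clusters = np.array([0] * 50 + [1] * 150)
        z = cluster_survival_zscore(clusters, clin, reps=500, seed=1)
        assert z.set_index("cluster").loc[0, "z"] < -3

    def test_whole_cohort_cluster_near_zero(self):
        clin = self._cohort(1)
        rng = np.random.default_rng(2)
        clusters = rng.integers(0, 4, size=len(clin))
        z = cluster_survival_zscore(clusters, clin, reps=500, seed=3)
        assert np.all(np.abs(z["z"].dropna()) < 3.5)

    def test_invariant_under_cluster_relabeling(self):
        clin = self._cohort(4)
        rng = np.random.default_rng(5)
        clusters = rng.integers(0, 3, size=len(clin))
        z1 = cluster_survival_zscore(clusters, clin, reps=300, seed=6)
        z2 = cluster_survival_zscore(10 - clusters, clin, reps=300, seed=6)
        merged = z1.assign(cluster=10 - z1["cluster"]).sort_values("cluster")
        assert np.allclose(merged["z"].to_numpy(),
                           z2.sort_values("cluster")["z"].to_numpy())
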