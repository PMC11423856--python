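"""Survival machinery against hand-computed and independent oracles."""

import numpy as np
import pandas as pd
import pytest

from sclc_subtyping.survival import (
    chemo_benefit_analysis,
    cox_ph,
    hazard_order,
    ici_analysis,
    ihc_score,
    km_estimate,
    logrank_test,
    subtype_names,
)


class TestKaplanMeier:
    def test_all_events_product_limit_by_hand(self):
        km = km_estimate([1.0, 2.0, 3.0], [True, True, True])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_is_flat_one(self):
        km = km_estimate([1.0, 2.0], [False, False])
        assert km.times.size == 0
        assert km.survival_at(5.0) == 1.0

    def test_eight_subject_fixture_manual_oracle(self):
        # times: events at 1, 2, 4, 5; censorings at 2, 3, 6; event at 7
        times = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        events = np.array([1, 1, 0, 0, 1, 1, 0, 1], dtype=bool)
        km = km_estimate(times, events)
        # manual product over risk sets:
        # t=1: 8 at risk, 1 event -> 7/8
        # t=2: 7 at risk (censored-at-2 still at risk), 1 event -> 7/8 * 6/7
        # t=4: 4 at risk, 1 event -> ... * 3/4
        # t=5: 3 at risk, 1 event -> ... * 2/3
        # t=7: 1 at risk, 1 event -> 0
        expected = np.array([
            7 / 8,
            7 / 8 * 6 / 7,
            7 / 8 * 6 / 7 * 3 / 4,
            7 / 8 * 6 / 7 * 3 / 4 * 2 / 3,
            0.0,
        ])
        np.testing.assert_allclose(km.survival, expected, atol=1e-12)
        np.testing.assert_array_equal(km.times, [1, 2, 4, 5, 7])
        np.testing.assert_array_equal(km.at_risk, [8, 7, 4, 3, 1])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(2.0, 200)
        km = km_estimate(t, np.ones(200, dtype=bool))
        for q in (0.5, 1.0, 3.0):
            assert km.survival_at(q) == pytest.approx((t > q).mean())

    def test_greenwood_variance_hand_checked(self):
        km = km_estimate([1.0, 2.0, 3.0, 4.0], [True, True, False, False])
        # t=1: S=3/4, var = S^2 * (1/(4*3)); t=2: S=1/2, var = S^2*(1/12+1/6)
        assert km.greenwood_var[0] == pytest.approx((3 / 4) ** 2 * (1 / 12))
        assert km.greenwood_var[1] == pytest.approx((1 / 2) ** 2 * (1 / 12 + 1 / 6))


def _contingency_logrank(times, events, groups):
    """Independent oracle: explicit 2xk table accumulation per event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    O = np.zeros(len(levels))
    E = np.zeros(len(levels))
    V = np.zeros((len(levels), len(levels)))
    for t in sorted(set(times[events])):
        n = (times >= t).sum()
        d = ((times == t) & events).sum()
        for a, ga in enumerate(levels):
            na = ((times >= t) & (groups == ga)).sum()
            O[a] += ((times == t) & events & (groups == ga)).sum()
            E[a] += d * na / n
            for b, gb in enumerate(levels):
                nb = ((times >= t) & (groups == gb)).sum()
                if n > 1:
                    V[a, b] += d * (n - d) / (n - 1) * (na / n) * (
                        (1.0 if a == b else 0.0) - nb / n
                    )
    u = (O - E)[:-1]
    stat = float(u @ np.linalg.pinv(V[:-1, :-1]) @ u)
    return stat


class TestLogrank:
    def test_duplicated_group_gives_zero(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [True] * 6
        g = [0, 0, 0, 1, 1, 1]
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_three_group_fixture_matches_oracle(self):
        rng = np.random.default_rng(42)
        t = np.concatenate([
            rng.exponential(1.0, 30),
            rng.exponential(2.0, 25),
            rng.exponential(4.0, 20),
        ])
        e = rng.random(75) > 0.2
        g = np.repeat([0, 1, 2], [30, 25, 20])
        res = logrank_test(t, e, g)
        assert res.df == 2
        assert res.statistic == pytest.approx(_contingency_logrank(t, e, g), abs=1e-10)

    def test_matches_lifelines(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(7)
        t = rng.exponential(1.0, 90)
        e = rng.random(90) > 0.3
        g = rng.integers(0, 3, 90)
        ours = logrank_test(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-8)
        assert ours.p_value == pytest.approx(ref.p_value, rel=1e-8)

    def test_power_on_separated_exponentials(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t = np.concatenate([rng.exponential(1.0, 200), rng.exponential(1 / 3, 200)])
            e = np.ones(400, dtype=bool)
            g = np.repeat([0, 1], 200)
            if logrank_test(t, e, g).p_value < 0.001:
                hits += 1
        assert hits >= 9

    def test_group_relabelling_invariance(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(1.0, 60)
        e = rng.random(60) > 0.3
        g = rng.integers(0, 3, 60)
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, np.array(["x", "z", "y"])[g])
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)


def _brute_force_cox_beta(times, events, x):
    """Grid-search maximiser of the (Breslow) partial likelihood, 1 covariate."""
    def pl(beta):
        ll = 0.0
        for i in np.flatnonzero(events):
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return ll

    grid = np.linspace(-5, 5, 20001)
    return grid[np.argmax([pl(b) for b in grid])]


class TestCox:
    def test_toy_dataset_matches_grid_search(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([True, True, True, False])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        fit = cox_ph(times, events, x[:, None], ties="breslow")
        oracle = _brute_force_cox_beta(times, events, x)
        assert fit.coef[0] == pytest.approx(oracle, abs=1e-3)
        # refine: gradient at fitted beta is ~0 is implied by NR convergence
        assert fit.hazard_ratio[0] == pytest.approx(np.exp(fit.coef[0]))

    def test_two_subject_one_event_flags_separation(self):
        # one event whose covariate exceeds the rest: partial likelihood is
        # monotone in beta (complete separation) and must be flagged
        fit = cox_ph([1.0, 2.0], [True, False], np.array([[1.0], [0.0]]))
        assert fit.separation_flag
        assert fit.coef[0] > 10

    def test_matches_lifelines_efron(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 120
        x = rng.normal(size=(n, 2))
        h = 0.3 * np.exp(0.8 * x[:, 0] - 0.4 * x[:, 1])
        t = np.round(rng.exponential(1 / h), 1) + 0.1  # rounding induces ties
        e = rng.random(n) > 0.25
        df = pd.DataFrame({"t": t, "e": e, "x0": x[:, 0], "x1": x[:, 1]})
        cph = CoxPHFitter().fit(df, "t", "e")
        fit = cox_ph(t, e, df[["x0", "x1"]], ties="efron")
        np.testing.assert_allclose(fit.coef, cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-5)

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(5)
        n = 80
        x = rng.normal(size=(n, 1))
        t = rng.exponential(1.0, n)  # continuous -> no ties a.s.
        e = rng.random(n) > 0.3
        fe = cox_ph(t, e, x, ties="efron")
        fb = cox_ph(t, e, x, ties="breslow")
        np.testing.assert_allclose(fe.coef, fb.coef, atol=1e-9)

    def test_sign_agrees_with_logrank_direction(self):
        rng = np.random.default_rng(8)
        g = np.repeat([0.0, 1.0], 100)
        t = np.where(g == 1, rng.exponential(0.5, 200), rng.exponential(2.0, 200))
        fit = cox_ph(t, np.ones(200, bool), g[:, None])
        assert fit.coef[0] > 0  # group 1 has higher hazard

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_ph([1.0, 2.0], [True, True], np.array([[1.0], [1.0]]))

    def test_null_covariate_ci_covers_one(self):
        covered = 0
        n_sim = 60
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(150, 1))
            t = rng.exponential(1.0, 150)
            e = rng.random(150) > 0.2
            fit = cox_ph(t, e, x)
            if fit.ci95_low[0] <= 1.0 <= fit.ci95_high[0]:
                covered += 1
        assert covered / n_sim >= 0.87


class TestClinicalAnalyses:
    @staticmethod
    def _clinical(n, tnm, chemo, times, events, rng=None):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "os_years": times,
                "os_event": events,
                "pfs_years": np.nan,
                "pfs_event": np.nan,
                "age": 60.0,
                "gender": "male",
                "smoking": True,
                "lnm": False,
                "tnm_stage": tnm,
                "valg_stage": "LS",
                "chemotherapy": chemo,
                "ici_line": "none",
            }
        )

    def test_restricted_to_tnm_two_three(self):
        tnm = ["I"] * 4 + ["II"] * 3 + ["III"] * 3
        clin = self._clinical(10, tnm, [True, False] * 5,
                              np.arange(1.0, 11.0), [True] * 10)
        out = chemo_benefit_analysis(clin, np.zeros(10, dtype=int))
        assert out.loc[0, "n_chemo"] + out.loc[0, "n_no_chemo"] == 6

    def test_empty_arm_not_evaluable(self):
        clin = self._clinical(6, ["II"] * 6, [False] * 6,
                              np.arange(1.0, 7.0), [True] * 6)
        out = chemo_benefit_analysis(clin, np.zeros(6, dtype=int))
        assert not out.loc[0, "evaluable"]
        assert np.isnan(out.loc[0, "logrank_p"])

    def test_ici_first_line_filter(self):
        clin = self._clinical(6, ["IV"] * 6, [False] * 6,
                              np.arange(1.0, 7.0), [True] * 6)
        clin["ici_line"] = ["first", "first", "first", "first", "none", "none"]
        clin["pfs_years"] = [0.5, 0.6, 1.5, 1.6, np.nan, np.nan]
        clin["pfs_event"] = [1.0, 1.0, 1.0, 1.0, np.nan, np.nan]
        labels = np.array([0, 0, 1, 1, 0, 1])
        out = ici_analysis(clin, labels)
        assert out.loc[0, "n"] == 4  # the two never-ICI samples never enter

    def test_ici_missing_pfs_rejected(self):
        clin = self._clinical(2, ["IV", "IV"], [False, False], [1.0, 2.0],
                              [True, True])
        clin["ici_line"] = ["first", "first"]
        with pytest.raises(ValueError, match="PFS"):
            ici_analysis(clin, np.array([0, 1]))


class TestIhcScore:
    @pytest.mark.parametrize(
        "intensity,percent,score,bin_,positive",
        [
            (3, 100.0, 300.0, "3+", True),
            (1, 5.0, 5.0, "0", False),
            (1, 41.0, 41.0, "2+", True),
            (1, 10.0, 10.0, "1+", False),  # bin 1+ but not positive
            (2, 70.0, 140.0, "2+", True),
            (3, 47.0, 141.0, "3+", True),
            (1, 11.0, 11.0, "1+", True),
        ],
    )
    def test_score_bins_and_positivity(self, intensity, percent, score, bin_, positive):
        s, b, pos = ihc_score(intensity, percent)
        assert (s, b, pos) == (score, bin_, positive)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ihc_score(4, 50.0)
        with pytest.raises(ValueError):
            ihc_score(2, 101.0)


class TestSubtypeNaming:
    def test_names_follow_hazard_order(self):
        rng = np.random.default_rng(2)
        labels = np.repeat(["a", "b", "c"], 50)
        haz = {"a": 0.7, "b": 0.06, "c": 0.2}
        t = np.concatenate([rng.exponential(1 / haz[g], 50) for g in ("a", "b", "c")])
        names = subtype_names(t, np.ones(150, bool), labels)
        assert names == {"b": "S-I", "c": "S-II", "a": "S-III"}
        assert hazard_order(t, np.ones(150, bool), labels) == ["b", "c", "a"]
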