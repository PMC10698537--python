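"""MELD, imputation, Cox screening/selection, bootstrap boosted-Cox, KM/log-rank oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from phccsurv.survival import (
    DEFAULT_IMPUTATION_RULES,
    compute_meld,
    concordance_index,
    feature_importance_distribution,
    filter_outcomes,
    fit_risk_model,
    impute_clinical,
    isgls_liver_failure,
    km_logrank_split,
    multivariable_cox,
    univariable_cox_screen,
)
from phccsurv.synthetic import CohortSpec, generate_cohort


class TestMeld:
    def test_additive_constant(self):
        assert compute_meld(1.0, 1.0, 1.0, False) == pytest.approx(6.43)

    def test_dialysis_substitutes_creatinine_4(self):
        assert compute_meld(1.0, 1.0, 1.0, True) == pytest.approx(6.43 + 9.57 * math.log(4.0))

    def test_unit_log_terms(self):
        e = math.e
        assert compute_meld(e, e, e) == pytest.approx(9.57 + 3.78 + 11.2 + 6.43)

    def test_nonpositive_lab_rejected(self):
        with pytest.raises(ValueError):
            compute_meld(0.0, 1.0, 1.0)


def test_isgls_flag_requires_both_elevations():
    assert isgls_liver_failure(1.5, 2.0)
    assert not isgls_liver_failure(1.5, 0.8)
    assert not isgls_liver_failure(1.0, 2.0)


class TestImputation:
    def _table(self):
        return pd.DataFrame(
            {
                "weight": [70.0, np.nan, 90.0],
                "height": [170.0, 180.0, np.nan],
                "ca19_9": [10.0, 20.0, np.nan],
                "ldh": [100.0, np.nan, 300.0],
                "days_diagnosis_to_surgery": [20.0, 40.0, np.nan],
                "biliary_stent": [1.0, np.nan, 0.0],
                "perineural_invasion": [np.nan, 1.0, 0.0],
                "uicc_stage": [2.0, np.nan, 3.0],
                "V": [np.nan, 1.0, 0.0],
                "L": [0.0, np.nan, 1.0],
                "T": [2.0, np.nan, 1.0],
                "G": [1.0, np.nan, 3.0],
            }
        )

    def test_default_rules(self):
        out = impute_clinical(self._table())
        assert out.loc[1, "weight"] == 80.0  # median of [70, 90]
        assert out.loc[1, "G"] == 2.0
        assert out.loc[1, "T"] == 0.0
        assert out.loc[1, "uicc_stage"] == 0.0
        assert out.loc[1, "biliary_stent"] == 0.0
        assert not out[list(DEFAULT_IMPUTATION_RULES)].isna().any().any()
        assert out.loc[1, "weight_imputed"] and not out.loc[0, "weight_imputed"]

    def test_median_uses_training_rows_only(self):
        t = pd.DataFrame({"weight": [50.0, np.nan, 500.0]})
        out = impute_clinical(t, {"weight": "median"}, train_mask=np.array([True, False, False]))
        assert out.loc[1, "weight"] == 50.0

    def test_missing_column_is_configuration_error(self):
        with pytest.raises(KeyError):
            impute_clinical(pd.DataFrame({"a": [1.0]}), {"weight": "median"})


def test_filter_outcomes_drops_ihm_and_r2():
    out = pd.DataFrame(
        {
            "time": [10, 20, 30, 40],
            "event": [1, 1, 0, 1],
            "in_hospital_death": [False, True, False, False],
            "r2_resection": [False, False, True, False],
        }
    )
    kept = filter_outcomes(out)
    assert kept.index.tolist() == [0, 3]


# ---------------------------------------------------------------------------
# classical Cox screening
# ---------------------------------------------------------------------------

def _sim_df(n, beta, seed, censor=0.003):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(beta)))
    coh = generate_cohort(CohortSpec(n_patients=n, beta=tuple(beta),
                                     censor_rate=censor, seed=seed + 1), X)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(len(beta))])
    df["time"], df["event"] = coh.time.values, coh.event.values
    return df


class TestUnivariableScreen:
    def test_null_flag_rate_near_alpha(self):
        """Independent covariate: ~5% flagged at alpha=.05 over 200 replicates."""
        flags = 0
        for r in range(200):
            df = _sim_df(80, [0.0], seed=3000 + r)
            scr = univariable_cox_screen(df, ["x0"])
            flags += int(scr.flagged.iloc[0])
        assert 0.02 <= flags / 200 <= 0.09

    def test_strong_effect_power(self):
        """HR=3 at n=200 flagged in >=95% of replicates."""
        hits = sum(
            univariable_cox_screen(_sim_df(200, [math.log(3)], seed=4000 + r), ["x0"]).flagged.iloc[0]
            for r in range(40)
        )
        assert hits >= 38

    def test_constant_covariate_skipped(self):
        df = _sim_df(50, [0.0], seed=1)
        df["const"] = 1.0
        with pytest.warns(UserWarning):
            scr = univariable_cox_screen(df, ["const", "x0"])
        assert scr.covariate.tolist() == ["x0"]

    def test_strict_alpha_inequality(self):
        """A covariate whose p equals alpha exactly is not flagged (p < alpha, strict)."""
        df = _sim_df(100, [0.8], seed=9)
        p = univariable_cox_screen(df, ["x0"]).p.iloc[0]
        scr = univariable_cox_screen(df, ["x0"], alpha=p)
        assert not scr.flagged.iloc[0]


class TestMultivariableCox:
    def test_single_strong_covariate_retained(self):
        df = _sim_df(150, [1.2], seed=5)
        summary, kept = multivariable_cox(df, ["x0"])
        assert kept == ["x0"]
        assert summary.p.iloc[0] < 0.05

    def test_collinear_copies_reduced_to_one(self):
        df = _sim_df(150, [1.2], seed=6)
        df["x0_copy"] = df["x0"]
        with pytest.warns(UserWarning):
            _, kept = multivariable_cox(df, ["x0", "x0_copy"])
        assert kept == ["x0"]

    def test_true_effects_recovered_among_noise(self):
        """3 true effects among 10 candidates retained in the majority of replicates."""
        recovered = 0
        for r in range(5):
            beta = [1.0, 1.0, 1.0] + [0.0] * 7
            df = _sim_df(300, beta, seed=7000 + r)
            _, kept = multivariable_cox(df, [f"x{i}" for i in range(10)])
            recovered += {"x0", "x1", "x2"} <= set(kept)
        assert recovered >= 3

    def test_no_survivor_returns_empty_model(self):
        df = _sim_df(60, [0.0], seed=8)
        summary, kept = multivariable_cox(df, ["x0"])
        assert kept == [] and summary.empty


# ---------------------------------------------------------------------------
# concordance / KM / log-rank oracles
# ---------------------------------------------------------------------------

def brute_concordance(time, event, risk):
    """All-pairs concordance over comparable pairs (small-n oracle)."""
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if event[i] and time[i] < time[j]:
                den += 1
                num += 1.0 if risk[i] > risk[j] else (0.5 if risk[i] == risk[j] else 0.0)
    return num / den


def brute_logrank(time, event, group):
    """Two-sample log-rank statistic by direct hypergeometric summation."""
    o_minus_e = v = 0.0
    for t in sorted(set(time[event.astype(bool)])):
        at_risk = time >= t
        n, n1 = at_risk.sum(), (at_risk & group).sum()
        d = ((time == t) & event.astype(bool)).sum()
        d1 = ((time == t) & event.astype(bool) & group).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / v


class TestConcordance:
    def test_matches_brute_force_small_n(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(4, 11))
            time = rng.random(n) * 100
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                event[0] = 1
            risk = rng.normal(size=n)
            assert concordance_index(time, event, risk) == pytest.approx(
                brute_concordance(time, event, risk), abs=1e-12)

    def test_perfect_ranking_no_censoring(self):
        time = np.array([5.0, 3.0, 8.0, 1.0])
        assert concordance_index(time, np.ones(4), -time) == 1.0


class TestKMLogrank:
    def _outcomes(self, time, event, ids=None):
        idx = ids if ids is not None else [f"P{i}" for i in range(len(time))]
        return pd.DataFrame({"time": time, "event": event}, index=idx)

    def test_hand_computed_km_and_logrank_six_patients(self):
        """KM estimates and the log-rank statistic match hand arithmetic."""
        time = np.array([2.0, 4.0, 5.0, 1.0, 3.0, 6.0])
        event = np.array([1, 1, 0, 1, 1, 1])
        risk = pd.Series([0.1, 0.2, 0.3, 0.9, 0.8, 0.7],
                         index=[f"P{i}" for i in range(6)])
        out = self._outcomes(time, event)
        res = km_logrank_split(risk, out)
        # low group: P0 (t=2, e), P1 (t=4, e), P2 (t=5, censored)
        # S(2) = 2/3, S(4) = 2/3 * 1/2 = 1/3, censor at 5 leaves S unchanged
        km = res.km_low.set_index("time")["survival"]
        assert km.loc[2.0] == pytest.approx(2 / 3)
        assert km.loc[4.0] == pytest.approx(1 / 3)
        assert km.loc[5.0] == pytest.approx(1 / 3)
        group = np.array([True, True, True, False, False, False])  # low group
        assert res.logrank_stat == pytest.approx(brute_logrank(time, event, group), abs=1e-9)

    def test_logrank_matches_brute_force_random(self):
        rng = np.random.default_rng(1)
        time = rng.random(10) * 50
        event = np.array([1, 1, 1, 0, 1, 1, 0, 1, 1, 1])
        risk = pd.Series(rng.normal(size=10), index=[f"P{i}" for i in range(10)])
        res = km_logrank_split(risk, self._outcomes(time, event))
        group = risk.values <= res.median_risk
        assert res.logrank_stat == pytest.approx(brute_logrank(time, event, group), abs=1e-9)

    def test_km_without_censoring_is_empirical_survival(self):
        rng = np.random.default_rng(2)
        time = rng.random(20) * 10
        risk = pd.Series(rng.normal(size=20), index=[f"P{i}" for i in range(20)])
        res = km_logrank_split(risk, self._outcomes(time, np.ones(20)))
        low_t = np.sort(time[risk.values <= res.median_risk])
        for t, s in zip(res.km_low.time[1:], res.km_low.survival[1:]):
            assert s == pytest.approx((low_t > t).mean())

    def test_identical_groups_statistic_near_zero(self):
        time = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        event = np.ones(8)
        risk = pd.Series(np.repeat([0.0, 1.0], 4), index=[f"P{i}" for i in range(8)])
        res = km_logrank_split(risk, self._outcomes(time, event))
        assert res.p_value > 0.5

    def test_identical_risks_error(self):
        risk = pd.Series(np.ones(6), index=[f"P{i}" for i in range(6)])
        with pytest.raises(ValueError, match="identical"):
            km_logrank_split(risk, self._outcomes(np.arange(6.0) + 1, np.ones(6)))

    def test_ties_assigned_to_low_group(self):
        risk = pd.Series([1.0, 1.0, 1.0, 2.0, 3.0],
                         index=[f"P{i}" for i in range(5)])
        res = km_logrank_split(risk, self._outcomes(np.arange(5.0) + 1, np.ones(5)))
        assert len(res.low_group) == 3  # median 1.0; ties go low


# ---------------------------------------------------------------------------
# bootstrap boosted Cox
# ---------------------------------------------------------------------------

def _features_outcomes(n, beta, seed):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, len(beta))),
                     columns=[f"f{i}" for i in range(len(beta))],
                     index=[f"P{i:03d}" for i in range(n)])
    coh = generate_cohort(CohortSpec(n_patients=n, beta=tuple(beta),
                                     censor_rate=0.003, seed=seed + 1), X.values)
    out = pd.DataFrame({"time": coh.time.values, "event": coh.event.values}, index=X.index)
    return X, out


class TestFitRiskModel:
    def test_single_round_deterministic(self):
        X, out = _features_outcomes(60, [1.0], seed=0)
        a = fit_risk_model(X, out, n_boot=1, seed=7)
        b = fit_risk_model(X, out, n_boot=1, seed=7)
        pd.testing.assert_series_equal(a.test_risk, b.test_risk)
        pd.testing.assert_series_equal(a.val_risk, b.val_risk)
        assert np.array_equal(a.test_ids, b.test_ids)

    def test_test_split_respects_given_ids(self):
        X, out = _features_outcomes(40, [1.0], seed=1)
        ids = X.index[:8]
        rs = fit_risk_model(X, out, n_boot=2, test_ids=ids, seed=0)
        assert sorted(rs.test_ids) == sorted(ids)
        assert not set(rs.test_ids) & set(rs.train_ids)

    def test_all_censored_training_fails(self):
        X, out = _features_outcomes(30, [0.0], seed=2)
        out["event"] = 0
        with pytest.raises(ValueError, match="censored"):
            fit_risk_model(X, out, n_boot=1, seed=0)

    def test_importances_sum_to_one_per_round(self):
        X, out = _features_outcomes(80, [1.0, 0.0, 0.0], seed=3)
        rs = fit_risk_model(X, out, n_boot=5, seed=1)
        samples, summary = feature_importance_distribution(rs)
        assert np.allclose(samples.sum(axis=1), 1.0)
        assert summary.loc["f0", "median"] == summary["median"].max()

    def test_hpo_selects_and_records_params(self):
        X, out = _features_outcomes(60, [1.2], seed=4)
        rs = fit_risk_model(X, out, n_boot=3, hpo_budget=2, hpo_rounds=2, seed=5)
        assert set(rs.params) == {"n_estimators", "max_depth", "learning_rate", "subsample"}

    def test_non_tree_models_unsupported_for_importance(self):
        class Dummy:
            pass

        with pytest.raises(TypeError):
            feature_importance_distribution([Dummy()])
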