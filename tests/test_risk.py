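import numpy as np
import pandas as pd
import pytest

from cmsig import (
    ClinicalTable,
    CoxRiskModel,
    assign_groups,
    concordance_index,
    fit_cox,
    fit_risk_model,
    group_hazard_ratio,
    km_curve,
    load_bundle,
    logrank_test,
    risk_scores,
    save_bundle,
    time_dependent_roc,
    univariate_cox_screen,
    youden_cutoff,
)

from ._oracles import (
    cindex_pairs_oracle,
    efron_partial_loglik,
    grid_search_cox,
    logrank_oracle,
    uncensored_roc_oracle,
)


def clin(time, event, unit="months"):
    time = np.asarray(time, dtype=float)
    return ClinicalTable(
        [f"s{i}" for i in range(len(time))], time, np.asarray(event), time_unit=unit
    )


def cox_toy():
    """Fixed 12-record, 2-feature design with tied event times (exercises
    the Efron correction); hazards depend moderately on both features."""
    rng = np.random.default_rng(5)
    X = rng.normal(size=(12, 2))
    lam = 0.1 * np.exp(0.8 * X[:, 0] - 0.5 * X[:, 1])
    t = np.round(rng.exponential(1.0 / lam)) + 1.0  # rounding creates ties
    event = (rng.random(12) < 0.8).astype(int)
    return X, t, event


class TestUnivariateScreen:
    def test_zero_variance_feature_skipped(self):
        rng = np.random.default_rng(0)
        n = 40
        c = clin(rng.exponential(20, n) + 0.1, rng.integers(0, 2, n))
        feats = pd.DataFrame(
            {"flat": np.ones(n), "noise": rng.normal(size=n)},
            index=c.sample_ids,
        )
        retained, report = univariate_cox_screen(feats, c, alpha_keep=1.1)
        assert report.loc["flat", "skipped"]
        assert "flat" not in retained and "noise" in retained

    def test_planted_hazard_feature_retained(self):
        """A feature equal to the per-subject log-hazard (plus small noise)
        must survive the screen decisively."""
        rng = np.random.default_rng(1)
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(x)))
        c = clin(np.maximum(t, 1e-3), np.ones(n, dtype=int))
        feats = pd.DataFrame({"hazard": x + rng.normal(0, 0.1, n)}, index=c.sample_ids)
        retained, report = univariate_cox_screen(feats, c)
        assert retained == ["hazard"]
        assert report.loc["hazard", "p"] < 0.01

    def test_no_events_rejected(self):
        c = clin([1, 2, 3, 4], [0, 0, 0, 0])
        feats = pd.DataFrame({"x": [1.0, 2, 3, 4]}, index=c.sample_ids)
        with pytest.raises(ValueError, match="no events"):
            univariate_cox_screen(feats, c)

    def test_empty_retention_rejected(self):
        rng = np.random.default_rng(2)
        n = 50
        c = clin(rng.exponential(20, n) + 0.1, rng.integers(0, 2, n))
        feats = pd.DataFrame({"noise": rng.normal(size=n)}, index=c.sample_ids)
        with pytest.raises(ValueError, match="empty signature"):
            univariate_cox_screen(feats, c, alpha_keep=1e-12)


class TestFitCox:
    def test_matches_grid_search_oracle(self):
        X, t, event = cox_toy()
        c = clin(t, event)
        feats = pd.DataFrame(X, columns=["f1", "f2"], index=c.sample_ids)
        model = fit_cox(feats, c)
        # the oracle works on the same standardized design the fit used
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        beta_grid = grid_search_cox(Z, t, event)
        np.testing.assert_allclose(model.coefficients, beta_grid, atol=1e-3)
        # and the fitted point must not be improvable at grid resolution
        ll_fit = efron_partial_loglik(model.coefficients, Z, t, event)
        assert ll_fit >= efron_partial_loglik(beta_grid, Z, t, event) - 1e-6

    def test_replication_behaviour(self):
        """Duplicating every record: the Breslow partial likelihood's
        maximizer is exactly invariant (shown with the grid oracle), while
        the Efron fit moves only within its tie-approximation error."""
        from ._oracles import breslow_partial_loglik

        X, t, event = cox_toy()
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        Z2, t2, e2 = np.vstack([Z, Z]), np.concatenate([t, t]), np.concatenate([event, event])
        bres1 = grid_search_cox(Z, t, event, loglik=breslow_partial_loglik)
        bres2 = grid_search_cox(Z2, t2, e2, loglik=breslow_partial_loglik)
        np.testing.assert_allclose(bres1, bres2, atol=2e-3)
        c1 = clin(t, event)
        m1 = fit_cox(pd.DataFrame(X, columns=["f1", "f2"], index=c1.sample_ids), c1)
        c2 = clin(t2, e2)
        feats2 = pd.DataFrame(
            np.vstack([X, X]), columns=["f1", "f2"], index=c2.sample_ids
        )
        m2 = fit_cox(feats2, c2)
        # the duplicated Efron fit is still the exact maximizer of the
        # duplicated Efron likelihood ...
        np.testing.assert_allclose(
            m2.coefficients, grid_search_cox(Z2, t2, e2), atol=1e-3
        )
        # ... and sits within the tie-approximation error of the original
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, atol=0.1)

    def test_null_features_small_coefficients(self):
        """Features independent of survival get |beta| < 0.2 at large n."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 400
            c = clin(rng.exponential(20, n) + 1e-3, np.ones(n, dtype=int))
            feats = pd.DataFrame(
                rng.normal(size=(n, 3)), columns=list("abc"), index=c.sample_ids
            )
            m = fit_cox(feats, c)
            hits += int(np.all(np.abs(m.coefficients) < 0.2))
        assert hits >= 18

    def test_too_few_events_rejected(self):
        c = clin([1, 2, 3, 4], [1, 0, 0, 0])
        feats = pd.DataFrame(
            np.random.default_rng(0).normal(size=(4, 2)), columns=["a", "b"],
            index=c.sample_ids,
        )
        with pytest.raises(ValueError, match="events"):
            fit_cox(feats, c)


class TestRiskScores:
    def _model(self, beta, means=None, sds=None, ids=None):
        ids = ids or [f"f{i}" for i in range(len(beta))]
        return CoxRiskModel(
            ids,
            np.asarray(beta, dtype=float),
            np.zeros(len(beta)) if means is None else np.asarray(means, float),
            np.ones(len(beta)) if sds is None else np.asarray(sds, float),
        )

    def test_zero_model_zero_scores(self):
        m = self._model([0.0, 0.0])
        feats = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)), columns=m.feature_ids)
        assert (risk_scores(m, feats) == 0).all()

    def test_identity_case(self):
        m = self._model([1.0])
        feats = pd.DataFrame({"f0": [-1.0, 0.0, 1.0]})
        np.testing.assert_allclose(risk_scores(m, feats), [-1, 0, 1])

    def test_shift_effect_closed_form(self):
        """Shifting a scoring-cohort feature by d changes RS by beta*d/sd."""
        m = self._model([0.7], means=[2.0], sds=[4.0])
        feats = pd.DataFrame({"f0": [1.0, 3.0, 9.0]})
        rs1 = risk_scores(m, feats)
        rs2 = risk_scores(m, feats + 10.0)
        np.testing.assert_allclose(rs2 - rs1, 0.7 * 10.0 / 4.0)

    def test_missing_feature_rejected(self):
        m = self._model([1.0, 2.0])
        feats = pd.DataFrame({"f0": [1.0, 2.0]})
        with pytest.raises(ValueError, match="f1"):
            risk_scores(m, feats)

    def test_bundle_round_trip(self, tmp_path):
        m = self._model([0.5, -1.2])
        m.cutoff = -0.14
        m.cutoff_horizon = 60.0
        p = tmp_path / "model.json"
        save_bundle(m.to_bundle(), p)
        back = CoxRiskModel.from_bundle(load_bundle(p))
        np.testing.assert_allclose(back.coefficients, m.coefficients, atol=1e-12)
        assert back.cutoff == m.cutoff


class TestTimeDependentRoc:
    def test_uncensored_toy_matches_counting(self):
        rs = np.array([2.1, -0.3, 0.8, 1.5, -1.0, 0.1])
        c = clin([2, 9, 4, 3, 12, 11], [1, 1, 1, 1, 1, 1])
        roc = time_dependent_roc(rs, c, horizon=5.0)
        case = (c.time <= 5.0) & (c.event == 1)
        for thr, sens, spec in zip(roc.thresholds, roc.sensitivity, roc.specificity):
            s, sp = uncensored_roc_oracle(rs, case, thr)
            assert sens == pytest.approx(s, abs=1e-12)
            assert spec == pytest.approx(sp, abs=1e-12)

    def test_perfect_separation_auc_one(self):
        rs = np.array([5.0, 4.0, 3.0, 0.0, -1.0, -2.0])
        c = clin([1, 2, 3, 50, 60, 70], [1, 1, 1, 1, 1, 1])
        roc = time_dependent_roc(rs, c, horizon=10.0)
        assert roc.auc == pytest.approx(1.0, abs=1e-12)

    def test_constant_score_auc_half(self):
        rs = np.zeros(8)
        c = clin([1, 2, 3, 4, 20, 30, 40, 50], [1, 1, 1, 1, 0, 0, 1, 0])
        roc = time_dependent_roc(rs, c, horizon=10.0)
        assert roc.auc == pytest.approx(0.5, abs=1e-12)

    def test_censoring_weights_against_sksurv(self):
        """Independent cross-check of the IPCW AUC on censored data."""
        from sksurv.metrics import cumulative_dynamic_auc

        rng = np.random.default_rng(6)
        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.8 * x)))
        cens = rng.uniform(0, 40, n)
        time = np.maximum(np.minimum(t, cens), 1e-3)
        event = (t <= cens).astype(int)
        c = clin(time, event)
        horizon = 15.0
        roc = time_dependent_roc(x, c, horizon)
        y = np.array(
            [(bool(e), ti) for e, ti in zip(event, time)],
            dtype=[("event", bool), ("time", float)],
        )
        auc_ref = float(cumulative_dynamic_auc(y, y, x, [horizon])[0][0])
        assert roc.auc == pytest.approx(auc_ref, abs=0.02)

    def test_no_events_before_horizon_rejected(self):
        c = clin([10, 20, 30, 40], [1, 1, 1, 1])
        with pytest.raises(ValueError, match="events before"):
            time_dependent_roc(np.arange(4.0), c, horizon=5.0)


class TestYouden:
    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = 30
            rs = np.round(rng.normal(size=n), 2)
            t = rng.exponential(20, n) + 1e-3
            e = rng.integers(0, 2, n)
            if ((t <= 12) & (e == 1)).sum() == 0 or (t > 12).sum() == 0:
                continue
            roc = time_dependent_roc(rs, clin(t, e), horizon=12.0)
            c_star, j = youden_cutoff(roc)
            # oracle: scan every threshold, keep max J, ties -> smaller threshold
            best = None
            for thr, s, sp in zip(roc.thresholds, roc.sensitivity, roc.specificity):
                jj = s + sp - 1
                if best is None or jj > best[0] + 1e-12 or (
                    abs(jj - best[0]) <= 1e-12 and thr < best[1]
                ):
                    best = (jj, thr)
            assert c_star == pytest.approx(best[1])
            assert j == pytest.approx(best[0])

    def test_perfect_separation_tie_rule(self):
        rs = np.array([3.0, 2.0, -1.0, -2.0])
        c = clin([1, 2, 50, 60], [1, 1, 1, 1])
        roc = time_dependent_roc(rs, c, horizon=10.0)
        c_star, j = youden_cutoff(roc)
        assert j == pytest.approx(1.0)
        assert c_star == 2.0  # smallest threshold achieving J = 1

    def test_constant_score_j_zero(self):
        rs = np.zeros(6)
        c = clin([1, 2, 3, 40, 50, 60], [1, 1, 1, 0, 0, 1], )
        roc = time_dependent_roc(rs, c, horizon=10.0)
        _, j = youden_cutoff(roc)
        assert j == pytest.approx(0.0)


class TestKmAndLogrank:
    def test_hand_product_limit_toy(self):
        c = clin([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1])
        km = km_curve(c)
        np.testing.assert_array_equal(km.times, [1, 2, 4, 6])
        np.testing.assert_allclose(km.survival, [5 / 6, 2 / 3, 4 / 9, 0.0])
        np.testing.assert_array_equal(km.at_risk, [6, 5, 3, 1])

    def test_no_events_survival_one(self):
        c = clin([1, 2, 3], [0, 0, 0])
        km = km_curve(c)
        assert km.times.size == 0  # no drops: S stays at 1 throughout

    def test_all_events_reach_zero(self):
        c = clin([1, 2, 3, 4], [1, 1, 1, 1])
        km = km_curve(c)
        assert km.survival[-1] == pytest.approx(0.0)

    def test_logrank_identical_groups_zero(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 0, 1, 1, 0]
        c = clin(t + t, e + e)
        stat, p = logrank_test(c, ["a"] * 5 + ["b"] * 5)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_logrank_label_symmetry(self):
        rng = np.random.default_rng(0)
        c = clin(rng.exponential(10, 30) + 1e-3, rng.integers(0, 2, 30))
        g = np.array(["a"] * 15 + ["b"] * 15, dtype=object)
        s1, _ = logrank_test(c, g)
        swapped = np.where(g == "a", "b", "a").astype(object)
        s2, _ = logrank_test(c, swapped)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_logrank_matches_hand_tabulation(self):
        time = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        event = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        groups = np.array(["a", "b", "a", "b", "a", "b", "a", "b"], dtype=object)
        c = clin(time, event)
        stat, _ = logrank_test(c, groups)
        want = logrank_oracle(time, event, groups == "a")
        assert stat == pytest.approx(want, rel=1e-9)


class TestHazardRatioAndConcordance:
    def test_ci_contains_point(self):
        rng = np.random.default_rng(1)
        n = 100
        c = clin(rng.exponential(20, n) + 1e-3, np.ones(n, dtype=int))
        g = np.array(["high"] * 50 + ["low"] * 50, dtype=object)
        res = group_hazard_ratio(c, g)
        assert res["ci_low"] <= res["hr"] <= res["ci_high"]

    def test_identical_groups_hr_near_one(self):
        rng = np.random.default_rng(2)
        n = 600
        c = clin(rng.exponential(20, n) + 1e-3, np.ones(n, dtype=int))
        g = np.array(["high", "low"] * (n // 2), dtype=object)
        res = group_hazard_ratio(c, g)
        assert 0.8 <= res["hr"] <= 1.25

    def test_rate_ratio_recovered(self):
        hrs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 600
            g = np.array(["high"] * (n // 2) + ["low"] * (n // 2), dtype=object)
            rate = np.where(g == "high", 0.05 * 2.5, 0.05)
            c = clin(np.maximum(rng.exponential(1.0 / rate), 1e-3), np.ones(n, dtype=int))
            hrs.append(group_hazard_ratio(c, g)["hr"])
        assert 2.0 <= np.mean(hrs) <= 3.1

    def test_perfect_concordance(self):
        t = np.array([5.0, 3, 8, 1, 9])
        c = clin(t, np.ones(5, dtype=int))
        assert concordance_index(-t, c) == pytest.approx(1.0)

    def test_constant_score_half(self):
        c = clin([1, 2, 3, 4], [1, 1, 1, 1])
        assert concordance_index(np.zeros(4), c) == pytest.approx(0.5)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = 30
            t = rng.exponential(20, n) + 1e-3  # continuous: no ties
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                continue
            rs = rng.normal(size=n)
            c = clin(t, e)
            assert concordance_index(rs, c) == pytest.approx(
                cindex_pairs_oracle(rs, t, e), abs=1e-12
            )


class TestFullRiskPipeline:
    def _cohort(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        lam = 0.03 * np.exp(0.9 * x1)
        t = rng.exponential(1.0 / lam)
        cens = rng.uniform(0, 80, n)
        time = np.maximum(np.minimum(t, cens), 1e-3)
        event = (t <= cens).astype(int)
        c = clin(time, event)
        feats = pd.DataFrame({"signal": x1, "noise": x2}, index=c.sample_ids)
        return feats, c

    def test_fit_and_groups(self):
        feats, c = self._cohort()
        model, assignment, screen = fit_risk_model(feats, c, horizon=30.0)
        assert "signal" in model.feature_ids
        assert set(assignment.group) == {"high", "low"}
        # group boundary respects RS >= cutoff
        hi = assignment.risk_score >= model.cutoff
        np.testing.assert_array_equal(assignment.group == "high", hi)

    def test_cutoff_invariant_to_score_rescaling(self):
        """Scaling all coefficients by c > 0 rescales RS but reproduces the
        same groups once the cutoff is recomputed (J is rank-based)."""
        feats, c = self._cohort(seed=5)
        model, assignment, _ = fit_risk_model(feats, c, horizon=30.0)
        scaled = CoxRiskModel(
            model.feature_ids,
            3.7 * model.coefficients,
            model.feature_means,
            model.feature_sds,
        )
        rs2 = risk_scores(scaled, feats)
        roc2 = time_dependent_roc(rs2, c, 30.0)
        scaled.cutoff, _ = youden_cutoff(roc2)
        a2 = assign_groups(scaled, feats)
        np.testing.assert_array_equal(assignment.group, a2.group)

    def test_heldout_c_index_above_chance(self):
        feats, c = self._cohort(seed=1)
        model, _, _ = fit_risk_model(feats, c, horizon=30.0)
        feats2, c2 = self._cohort(seed=2)
        rs = risk_scores(model, feats2)
        cidx = concordance_index(rs, c2)
        n_pairs = len(c2) * (len(c2) - 1) / 2
        se = 3.0 / np.sqrt(n_pairs)  # generous detection floor
        assert cidx > 0.5 + 3 * se
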