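import numpy as np
import pandas as pd
import pytest

from milsurv.cohort import SurvivalLabel
from milsurv.stats import (
    concordance_index,
    cox_fit,
    dichotomize_by_median,
    kaplan_meier,
    staged_analysis,
)


def brute_force_cindex(o, t, d, restrict=True):
    """Naive pair loop implementing (C + R/2)/(C + D + R)."""
    C = D = R = 0
    n = len(o)
    for i in range(n):
        for j in range(n):
            if t[i] < t[j] and (d[i] == 1 or not restrict):
                if o[i] > o[j]:
                    C += 1
                elif o[i] < o[j]:
                    D += 1
                else:
                    R += 1
    if C + D + R == 0:
        return None
    return (C + R / 2) / (C + D + R)


class TestConcordance:
    def test_perfect_ordering(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        res = concordance_index(np.array([4.0, 3.0, 2.0, 1.0]), (t, np.ones(4, int)))
        assert res.c_hat == 1.0 and res.discordant == 0

    def test_all_tied_risks_half(self):
        t = np.array([1.0, 2.0, 3.0])
        res = concordance_index(np.zeros(3), (t, np.ones(3, int)))
        assert res.c_hat == 0.5
        assert res.tied_risk == res.n_permissible == 3

    def test_hand_enumerated_toy(self):
        o = np.array([2.0, 1.0, 3.0])
        t = np.array([1.0, 2.0, 3.0])
        res = concordance_index(o, (t, np.ones(3, int)))
        assert (res.concordant, res.discordant, res.tied_risk) == (1, 2, 0)
        assert res.c_hat == pytest.approx(1 / 3)

    def test_against_bruteforce_with_censoring(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 60))
            o = rng.choice([0.1, 0.5, 0.9, 1.3], size=n)  # force ties
            t = rng.exponential(1, n).round(1)  # force tied times too
            d = (rng.random(n) < 0.6).astype(int)
            expected = brute_force_cindex(o, t, d)
            if expected is None:
                with pytest.raises(ValueError):
                    concordance_index(o, (t, d))
            else:
                assert concordance_index(o, (t, d)).c_hat == expected

    def test_symmetry_under_risk_negation(self, rng):
        n = 50
        o = rng.standard_normal(n)
        t = rng.exponential(1, n)
        d = (rng.random(n) < 0.7).astype(int)
        a = concordance_index(o, (t, d))
        b = concordance_index(-o, (t, d))
        assert a.tied_risk == 0
        assert a.c_hat + b.c_hat == pytest.approx(1.0)

    def test_matches_sksurv(self, rng):
        from sksurv.metrics import concordance_index_censored

        n = 120
        o = rng.standard_normal(n)
        t = rng.exponential(1, n)
        d = (rng.random(n) < 0.6).astype(int)
        ours = concordance_index(o, (t, d)).c_hat
        theirs = concordance_index_censored(d.astype(bool), t, o)[0]
        assert ours == pytest.approx(theirs, abs=1e-12)


class TestDichotomize:
    def test_median_cutoff(self):
        high, cutoff = dichotomize_by_median([0.1, 0.2, 0.3, 0.4])
        assert cutoff == pytest.approx(0.25)
        assert high.tolist() == [False, False, True, True]

    def test_all_equal_all_low(self):
        high, _ = dichotomize_by_median([0.7] * 5)
        assert not high.any()

    def test_balanced_split_for_distinct_values(self, rng):
        o = rng.standard_normal(240)
        high, _ = dichotomize_by_median(o)
        assert abs(int(high.sum()) - int((~high).sum())) <= 1
        assert high.sum() + (~high).sum() == 240


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        curves = kaplan_meier((np.array([1.0, 2.0, 3.0]), np.zeros(3, int)))
        assert (curves["all"].survival == 1.0).all()

    def test_three_patient_product_limit_by_hand(self):
        curves = kaplan_meier((np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0])))
        c = curves["all"]
        assert c.survival_at(1.0) == pytest.approx(2 / 3)
        assert c.survival_at(2.0) == pytest.approx(1 / 3)
        assert c.survival_at(3.0) == pytest.approx(1 / 3)

    def test_single_event_drops_to_zero(self):
        c = kaplan_meier((np.array([2.0]), np.array([1])))["all"]
        assert c.survival_at(2.0) == 0.0

    def test_monotone_nonincreasing_in_unit_interval(self, rng):
        t = rng.exponential(2, 80)
        d = (rng.random(80) < 0.6).astype(int)
        c = kaplan_meier((t, d))["all"]
        assert (np.diff(c.survival) <= 1e-12).all()
        assert ((c.survival >= 0) & (c.survival <= 1)).all()

    def test_groups_and_censoring_reduce_at_risk_without_step(self):
        t = np.array([1.0, 1.5, 2.0, 3.0])
        d = np.array([1, 0, 1, 0])
        g = np.array(["a", "a", "a", "b"])
        curves = kaplan_meier((t, d), g)
        a = curves["a"]
        # group a: event at 1 (n=3), censor at 1.5 (no step), event at 2 with
        # only one patient left -> S: 2/3 after t=1, 0 after t=2
        assert a.survival_at(1.0) == pytest.approx(2 / 3)
        assert a.survival_at(1.7) == pytest.approx(2 / 3)
        assert a.survival_at(2.0) == pytest.approx(0.0)


class TestCoxFit:
    def test_null_covariate_behaviour(self, rng):
        hits = 0
        for _ in range(40):
            n = 150
            x = rng.standard_normal(n)
            t = rng.exponential(1, n)
            d = (rng.random(n) < 0.7).astype(int)
            fit = cox_fit(x, (t, d))
            if fit.p[0] > 0.05:
                hits += 1
        assert hits >= 32  # ~95% of null fits should be non-significant

    def test_binary_covariate_recovers_true_hr3(self, rng):
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        t_event = rng.exponential(1.0 / (0.1 * np.exp(np.log(3.0) * x)))
        c = rng.exponential(1.0 / 0.045, n)
        t = np.minimum(t_event, c)
        d = (t_event <= c).astype(int)
        assert 0.2 < 1 - d.mean() < 0.45
        fit = cox_fit(x, (t, d))
        assert fit.coef[0] == pytest.approx(np.log(3.0), abs=0.15)
        assert fit.ci_low[0] <= fit.hr[0] <= fit.ci_high[0]

    def test_grid_scan_agrees_on_ten_patient_toy(self, rng):
        from milsurv.objectives import npll_loss

        x = rng.standard_normal(10)
        t = rng.exponential(np.exp(-x))
        d = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 1])
        fit = cox_fit(x, (t, d))
        grid = np.arange(-5, 5, 1e-4)
        losses = [npll_loss(b * x, (t, d)) for b in grid]
        assert fit.coef[0] == pytest.approx(grid[int(np.argmin(losses))], abs=1e-4)

    def test_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter

        n = 300
        X = rng.standard_normal((n, 2))
        t = rng.exponential(np.exp(-(0.5 * X[:, 0] - 0.3 * X[:, 1])))
        d = (rng.random(n) < 0.8).astype(int)
        ours = cox_fit(X, (t, d))
        df = pd.DataFrame({"x0": X[:, 0], "x1": X[:, 1], "t": t, "d": d})
        ll = CoxPHFitter().fit(df, duration_col="t", event_col="d")
        np.testing.assert_allclose(ours.coef, ll.params_.values, atol=1e-4)
        np.testing.assert_allclose(ours.se, ll.standard_errors_.values, atol=1e-4)

    def test_univariate_mode_fits_each_column(self, rng):
        X = rng.standard_normal((100, 3))
        t = rng.exponential(1, 100)
        d = np.ones(100, int)
        fits = cox_fit(X, (t, d), mode="univariate", names=["a", "b", "c"])
        assert [f.names[0] for f in fits] == ["a", "b", "c"]
        assert all(len(f.coef) == 1 for f in fits)

    def test_separation_flagged_not_raised(self):
        # covariate perfectly ordered with event times -> beta diverges
        n = 30
        x = np.linspace(1, 0, n)
        t = np.linspace(1, 30, n)
        d = np.ones(n, int)
        fit = cox_fit(x, (t, d))
        assert not fit.converged


class TestStagedAnalysis:
    def _setup(self, constant_risk=False, seed=0):
        rng = np.random.default_rng(seed)
        n = 120
        ids = [f"P{i}" for i in range(n)]
        risk = np.zeros(n) if constant_risk else rng.standard_normal(n)
        t = rng.exponential(np.exp(-risk))
        d = (rng.random(n) < 0.7).astype(int)
        labels = {pid: SurvivalLabel(float(t[i]), int(d[i])) for i, pid in enumerate(ids)}
        roles = {
            pid: ("test" if i < 30 else "val" if i < 60 else "train")
            for i, pid in enumerate(ids)
        }
        risks = dict(zip(ids, risk))
        return risks, labels, roles

    def test_true_risk_model_gives_hr_above_one_stage3(self):
        risks, labels, roles = self._setup()
        report = staged_analysis(risks, labels, roles)
        row = report.table[(report.table.stage == 3) & (report.table.parameter == "MIL")]
        assert float(row.HR.iloc[0]) > 1.0
        assert float(row.CI_low.iloc[0]) > 1.0  # CI excludes 1 by construction

    def test_constant_risk_flagged_degenerate(self):
        risks, labels, roles = self._setup(constant_risk=True)
        with pytest.warns(UserWarning, match="constant"):
            report = staged_analysis(risks, labels, roles)
        assert report.table.HR.isna().all()

    def test_stage_cutoffs_differ_across_subsets(self):
        risks, labels, roles = self._setup()
        report = staged_analysis(risks, labels, roles)
        assert len(set(report.cutoffs.values())) == 3

    def test_stage_membership_counts(self):
        risks, labels, roles = self._setup()
        report = staged_analysis(risks, labels, roles)
        mil = report.table[report.table.parameter == "MIL"]
        sizes = {int(r.stage): int(r.n_high + r.n_low) for r in mil.itertuples()}
        assert sizes == {1: 30, 2: 60, 3: 120}

    def test_multivariate_includes_clinical_covariates(self):
        risks, labels, roles = self._setup()
        rng = np.random.default_rng(1)
        cov = pd.DataFrame(
            {"age_gt_55": rng.integers(0, 2, 120), "ln_positive": rng.integers(0, 2, 120)},
            index=list(risks),
        )
        report = staged_analysis(risks, labels, roles, clinical_covariates=cov)
        multi = report.table[report.table.analysis == "multivariate"]
        assert set(multi.parameter) == {"MIL", "age_gt_55", "ln_positive"}
        km_groups = {g for (_, g) in report.km}
        assert km_groups == {"high", "low"}
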