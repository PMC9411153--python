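import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from milsurv.cohort import SurvivalLabel
from milsurv.objectives import (
    TrainConfig,
    comparable_pairs,
    npll_gradient,
    npll_loss,
    rank_loss,
    risk_sets,
    train,
)
from milsurv.simulate import SimConfig, simulate_cohort
from milsurv.stats import concordance_index, cox_fit
from milsurv.objectives import predict_risks


def naive_npll(o, t, d):
    """Brute-force double loop over the partial likelihood (no LSE trick)."""
    total = 0.0
    for i in range(len(o)):
        if d[i] == 1:
            z = sum(np.exp(o[j]) for j in range(len(o)) if t[j] >= t[i])
            total += -o[i] + np.log(z)
    return total


class TestNpll:
    def test_no_events_zero_loss(self):
        assert npll_loss(np.array([1.0, -2.0]), (np.array([1.0, 2.0]), np.array([0, 0]))) == 0.0

    def test_equal_risk_toy_is_ln3(self):
        t, d = np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1])
        assert npll_loss(np.zeros(3), (t, d)) == pytest.approx(np.log(3), abs=1e-12)

    def test_matches_naive_double_loop(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 12))
            o = rng.normal(0, 1, n)
            t = rng.exponential(1, n)
            d = (rng.random(n) < 0.6).astype(int)
            assert npll_loss(o, (t, d)) == pytest.approx(naive_npll(o, t, d), abs=1e-10)

    def test_shift_invariance(self, rng):
        o = rng.normal(0, 2, 15)
        t = rng.exponential(1, 15)
        d = (rng.random(15) < 0.5).astype(int)
        assert npll_loss(o, (t, d)) == pytest.approx(npll_loss(o + 37.5, (t, d)), abs=1e-8)

    def test_nonnegative_and_order_only(self, rng):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        d = np.array([1, 1, 0, 1])
        o = rng.normal(size=4)
        base = npll_loss(o, (t, d))
        assert base >= 0
        assert npll_loss(o, (t * 100 + 3, d)) == pytest.approx(base, abs=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        n = 10
        o = rng.normal(0, 1, n)
        t = rng.exponential(1, n)
        d = (rng.random(n) < 0.5).astype(int)
        d[rng.integers(n)] = 1
        g = npll_gradient(o, (t, d))
        eps = 1e-6
        for i in range(n):
            e = np.zeros(n)
            e[i] = eps
            fd = (npll_loss(o + e, (t, d)) - npll_loss(o - e, (t, d))) / (2 * eps)
            assert abs(fd - g[i]) / max(abs(fd), 1e-8) < 1e-4

    def test_nan_risk_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            npll_loss(np.array([np.nan, 0.0]), (np.array([1.0, 2.0]), np.array([1, 0])))

    def test_breslow_ties_full_risk_set(self):
        # two tied events at t=1: each contributes log(3) at equal risks
        t, d = np.array([1.0, 1.0, 2.0]), np.array([1, 1, 0])
        assert npll_loss(np.zeros(3), (t, d)) == pytest.approx(2 * np.log(3), abs=1e-12)

    def test_risk_sets_antimonotone_and_include_self(self):
        t, d = np.array([3.0, 1.0, 2.0]), np.array([1, 1, 1])
        rs = risk_sets((t, d))
        assert set(rs[1]) == {0, 1, 2} and set(rs[2]) == {0, 2} and set(rs[0]) == {0}


class TestRankLoss:
    def test_equal_risks_ln2(self):
        assert rank_loss(1.3, 1.3) == pytest.approx(np.log(2), abs=1e-12)

    def test_unit_margin(self):
        assert rank_loss(1.0, 0.0) == pytest.approx(np.log(1 + np.exp(-1)), abs=1e-12)

    def test_monotone_decreasing_to_zero(self):
        grid = np.linspace(-5, 20, 60)
        vals = [rank_loss(x, 0.0) for x in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-8


class TestComparablePairs:
    def test_all_censored_empty(self):
        assert comparable_pairs((np.array([1.0, 2.0]), np.array([0, 0]))) == []

    def test_two_events(self):
        assert comparable_pairs((np.array([1.0, 2.0]), np.array([1, 1]))) == [(0, 1)]

    def test_enumeration_against_rule(self):
        t, d = np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1])
        pairs = comparable_pairs((t, d))
        assert set(pairs) == {(0, 1), (0, 2)}
        # exhaustive check of the rule over all ordered pairs
        expected = {
            (i, j) for i in range(3) for j in range(3) if d[i] == 1 and t[i] < t[j]
        }
        assert set(pairs) == expected


class TestTraining:
    def _tiny_cohort(self, beta, seed=5):
        return simulate_cohort(
            SimConfig(n_patients=60, instances_per_bag=(5, 8), d=8,
                      effect_beta=beta, seed=seed)
        )

    def test_identical_seeds_identical_loss_curves(self):
        cohort = self._tiny_cohort(beta=1.0)
        ids = [b.patient_id for b in cohort.bags]
        cfg = TrainConfig(learning_rate=1e-3, epochs=8, rank_loss_start_epoch=4, seed=3, M=4, L=4)
        a = train(cohort.bags, (ids[:40], ids[40:]), cfg, variant="instance")
        b = train(cohort.bags, (ids[:40], ids[40:]), cfg, variant="instance")
        assert a.log["train_npll"].tolist() == b.log["train_npll"].tolist()
        assert a.log["val_cindex"].tolist() == b.log["val_cindex"].tolist()

    def test_no_events_in_training_split_rejected(self):
        cohort = self._tiny_cohort(beta=0.0)
        censored = [b.patient_id for b in cohort.bags if b.label.event == 0][:20]
        others = [b.patient_id for b in cohort.bags if b.patient_id not in censored]
        cfg = TrainConfig(epochs=2, rank_loss_start_epoch=0, seed=0)
        with pytest.raises(ValueError, match="event"):
            train(cohort.bags, (censored, others), cfg, variant="instance")

    def test_null_cohort_validation_cindex_near_half(self):
        cohort = self._tiny_cohort(beta=0.0, seed=11)
        ids = [b.patient_id for b in cohort.bags]
        cfg = TrainConfig(learning_rate=1e-3, epochs=30, seed=1, M=4, L=4)
        res = train(cohort.bags, (ids[:40], ids[40:]), cfg, variant="instance")
        preds = predict_risks(
            [b for b in cohort.bags if b.patient_id in set(ids[40:])], res.final_params
        )
        c = concordance_index(
            [p.risk for p in preds],
            [b.label for b in cohort.bags if b.patient_id in set(ids[40:])],
        ).c_hat
        assert 0.25 < c < 0.75  # no learnable ordering exists

    def test_clustered_variant_trains(self):
        cohort = self._tiny_cohort(beta=1.5, seed=7)
        ids = [b.patient_id for b in cohort.bags]
        cfg = TrainConfig(learning_rate=1e-3, epochs=5, rank_loss_start_epoch=2, seed=2, M=4, L=4, k=3)
        res = train(cohort.bags, (ids[:40], ids[40:]), cfg, variant="clustered")
        assert np.isfinite(res.log["train_npll"]).all()
        assert res.log.shape[0] == 5

    def test_minibatch_scheme_runs(self):
        cohort = self._tiny_cohort(beta=1.0, seed=8)
        ids = [b.patient_id for b in cohort.bags]
        cfg = TrainConfig(
            learning_rate=1e-3, epochs=4, rank_loss_start_epoch=1, seed=2, M=4, L=4,
            batch_scheme="minibatch", batch_size=16,
        )
        res = train(cohort.bags, (ids[:45], ids[45:]), cfg, variant="instance")
        assert res.log.shape[0] == 4


class TestCoxNpllConsistency:
    def test_linear_model_npll_minimum_matches_cox_fit(self, rng):
        """Minimizing the NPLL of a linear risk recovers the Cox estimate."""
        n = 80
        x = rng.standard_normal(n)
        t = rng.exponential(np.exp(-0.8 * x))
        d = np.ones(n, dtype=int)
        res = minimize_scalar(lambda b: npll_loss(b * x, (t, d)), bounds=(-5, 5), method="bounded")
        fit = cox_fit(x, (t, d))
        assert res.x == pytest.approx(fit.coef[0], abs=0.1)
        # the loss at the fitted coefficient equals the negated max partial log-lik
        assert npll_loss(fit.coef[0] * x, (t, d)) == pytest.approx(
            -fit.log_likelihood, abs=1e-6
        )
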