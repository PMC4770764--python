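import itertools
import math

import numpy as np
import pytest

from mirisk.datamodel import SurvivalOutcome
from mirisk.errors import CutpointError, DivergenceError, FitError, GroupingError
from mirisk.survival_stats import (
    cox_fit,
    cox_loglik,
    dichotomize_and_compare,
    lausen_schumacher_p,
    logrank_test,
    maxstat_cutpoint,
    standardized_logrank,
)
from mirisk.synthetic_data import simulate_survival


def _outcomes(times, events):
    return [SurvivalOutcome(time=t, event=bool(e)) for t, e in zip(times, events)]


def naive_efron_loglik(beta, x, times, events):
    """Independent brute-force Efron partial log-likelihood (set-based)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != len(times):
        x = x.T
    eta = x @ beta
    w = np.exp(eta)
    ll = 0.0
    for t in sorted(set(t for t, e in zip(times, events) if e)):
        dead = [i for i in range(len(times)) if events[i] and times[i] == t]
        risk = [i for i in range(len(times)) if times[i] >= t]
        s_risk = sum(w[i] for i in risk)
        s_dead = sum(w[i] for i in dead)
        m = len(dead)
        for i in dead:
            ll += eta[i]
        for ell in range(m):
            ll -= math.log(s_risk - (ell / m) * s_dead)
    return ll


def naive_logrank_stat(group, times, events):
    """Independent observed-minus-expected log-rank computation."""
    u = 0.0
    v = 0.0
    for t in sorted(set(t for t, e in zip(times, events) if e)):
        risk = [i for i in range(len(times)) if times[i] >= t]
        dead = [i for i in risk if events[i] and times[i] == t]
        n = len(risk)
        n1 = sum(1 for i in risk if group[i])
        d = len(dead)
        d1 = sum(1 for i in dead if group[i])
        u += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return u, v


class TestCoxFit:
    def test_brute_force_grid_oracle_n8(self):
        # hand-listed small instance with a tie in the event times
        times = [2.0, 3.0, 3.0, 5.0, 7.0, 8.0, 11.0, 12.0]
        events = [1, 1, 1, 0, 1, 0, 1, 0]
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        fit = cox_fit(x[:, None], _outcomes(times, events))
        grid = np.linspace(-4, 4, 160001)
        lls = [naive_efron_loglik([b], x[:, None], times, events) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert abs(fit.coefficients[0] - best) < 1e-4

    @pytest.mark.parametrize("seed", range(4))
    def test_brute_force_oracle_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        times = np.round(rng.exponential(10, size=n), 1) + 0.5
        events = rng.random(n) < 0.7
        if not events.any():
            events[0] = True
        x = rng.normal(size=n)
        fit = cox_fit(x[:, None], _outcomes(times, events))
        grid = np.linspace(fit.coefficients[0] - 0.01, fit.coefficients[0] + 0.01, 2001)
        lls = [naive_efron_loglik([b], x[:, None], times, events) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert abs(fit.coefficients[0] - best) < 1e-4

    def test_matches_lifelines(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(1)
        x = rng.normal(size=(80, 2))
        out = simulate_survival(x[:, 0] - 0.5 * x[:, 1], loghr=0.8, censor_rate=0.3, seed=2)
        fit = cox_fit(x, out)
        df = pd.DataFrame(
            {"t": [o.time for o in out], "e": [o.event for o in out],
             "x0": x[:, 0], "x1": x[:, 1]}
        )
        cph = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.coefficients, cph.params_.values, atol=1e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values, atol=1e-5)

    def test_null_calibration(self):
        ok = 0
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=200)
            out = simulate_survival(
                rng.normal(size=200), loghr=0.5, censor_rate=0.3, seed=seed + 10_000
            )
            fit = cox_fit(x[:, None], out)
            if abs(fit.coefficients[0]) < 4 * fit.se[0]:
                ok += 1
        assert ok / n_seeds >= 0.95

    def test_local_optimum_on_grid(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        out = simulate_survival(x, loghr=0.5, censor_rate=0.2, seed=4)
        times = [o.time for o in out]
        events = [o.event for o in out]
        fit = cox_fit(x[:, None], out)
        b = fit.coefficients[0]
        ll_opt = naive_efron_loglik([b], x[:, None], times, events)
        for delta in (-0.05, -0.01, 0.01, 0.05):
            assert ll_opt >= naive_efron_loglik([b + delta], x[:, None], times, events)

    def test_internal_loglik_matches_naive(self):
        rng = np.random.default_rng(5)
        n = 15
        times = np.round(rng.exponential(5, size=n), 0) + 1.0  # force ties
        events = rng.random(n) < 0.6
        events[0] = True
        x = rng.normal(size=(n, 2))
        beta = np.array([0.3, -0.7])
        xc = x - x.mean(axis=0)
        assert cox_loglik(beta, xc, times, np.asarray(events)) == pytest.approx(
            naive_efron_loglik(beta, xc, times, events), rel=1e-10
        )

    def test_no_events_rejected(self):
        with pytest.raises(FitError):
            cox_fit(np.ones((4, 1)), _outcomes([1, 2, 3, 4], [0, 0, 0, 0]))

    def test_duplicated_covariate_singular(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        out = simulate_survival(x, loghr=0.5, censor_rate=0.2, seed=7)
        with pytest.raises(DivergenceError):
            cox_fit(np.column_stack([x, x]), out)

    def test_perfect_separation_diverges(self):
        # covariate orders samples exactly by event time with all events
        times = np.arange(1.0, 21.0)
        x = -times
        with pytest.raises(DivergenceError):
            cox_fit(x[:, None], _outcomes(times, np.ones(20)))


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [1.0, 2, 3, 1, 2, 3]
        events = [1, 1, 0, 1, 1, 0]
        group = [True, True, True, False, False, False]
        stat, p = logrank_test(group, _outcomes(times, events))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computable_six_sample_example(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 0, 1, 1, 0, 1]
        group = [True, False, True, False, True, False]
        stat, p = logrank_test(group, _outcomes(times, events))
        u, v = naive_logrank_stat(group, times, events)
        assert stat == pytest.approx(u * u / v, abs=1e-6)

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(8)
        out = simulate_survival(rng.normal(size=30), loghr=0.5, censor_rate=0.3, seed=9)
        g = rng.random(30) < 0.5
        s1, p1 = logrank_test(g, out)
        s2, p2 = logrank_test(~g, out)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_power_on_separated_groups(self):
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            g = np.arange(200) < 100
            out = simulate_survival(
                g.astype(float) * 1.5, loghr=1.0, censor_rate=0.2, seed=seed + 500
            )
            _, p = logrank_test(g, out)
            hits += p < 0.001
        assert hits / n_seeds >= 0.95

    def test_single_group_rejected(self):
        with pytest.raises(GroupingError):
            logrank_test([True, True], _outcomes([1, 2], [1, 1]))


class TestMaxstat:
    def _enumerate_best(self, x, outcomes, bounds=(0.1, 0.9)):
        """Independent exhaustive enumeration over in-bounds thresholds."""
        times = [o.time for o in outcomes]
        events = [o.event for o in outcomes]
        xs = np.asarray(x, dtype=float)
        best = (None, -1.0)
        for c in np.unique(xs)[:-1]:
            prop = (xs <= c).mean()
            if not (bounds[0] <= prop <= bounds[1]):
                continue
            u, v = naive_logrank_stat(list(xs > c), times, events)
            stat = abs(u) / math.sqrt(v) if v > 0 else 0.0
            if stat > best[1]:
                best = (float(c), stat)
        return best

    def test_constant_x_rejected(self):
        out = simulate_survival(np.zeros(12), loghr=0.0, censor_rate=0.2, seed=0)
        with pytest.raises(CutpointError):
            maxstat_cutpoint(np.ones(12), out)

    @pytest.mark.parametrize("seed", range(25))
    def test_exhaustive_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 16))
        x = np.round(rng.normal(size=n), 1)  # rounding induces ties
        out = simulate_survival(rng.normal(size=n), loghr=0.8, censor_rate=0.2,
                                seed=seed + 3000)
        try:
            res = maxstat_cutpoint(x, out)
        except CutpointError:
            return
        cut, stat = self._enumerate_best(x, out)
        assert res.max_stat == pytest.approx(stat, abs=1e-9)
        assert res.cutoff == pytest.approx(cut)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=40)
        out = simulate_survival(x, loghr=0.7, censor_rate=0.3, seed=11)
        res_raw = maxstat_cutpoint(x, out)
        res_exp = maxstat_cutpoint(np.exp(x), out)
        assert res_exp.max_stat == pytest.approx(res_raw.max_stat, abs=1e-9)
        assert res_exp.cutoff == pytest.approx(np.exp(res_raw.cutoff))

    def test_planted_threshold_recovery(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 300
            x = rng.normal(size=n)
            thresh = np.quantile(x, 0.6)
            out = simulate_survival(
                (x > thresh).astype(float), loghr=0.9, censor_rate=0.2, seed=seed + 7000
            )
            res = maxstat_cutpoint(x, out)
            recovered_pct = (x <= res.cutoff).mean()
            if abs(recovered_pct - 0.6) <= 0.10:
                hits += 1
        assert hits / n_seeds >= 0.8

    def test_lausen_schumacher_monotone_decreasing_in_b(self):
        ps = [lausen_schumacher_p(b, 0.1, 0.9) for b in np.linspace(1.5, 5, 30)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert lausen_schumacher_p(0.0, 0.1, 0.9) == 1.0

    def test_standardized_logrank_matches_naive(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=20)
        out = simulate_survival(x, loghr=0.3, censor_rate=0.3, seed=13)
        c = float(np.median(x))
        u, v = naive_logrank_stat(
            list(np.asarray(x) > c), [o.time for o in out], [o.event for o in out]
        )
        assert standardized_logrank(x, c, out) == pytest.approx(abs(u) / math.sqrt(v))


class TestDichotomizeAndCompare:
    def test_labels_partition_at_cutoff(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=10)
        out = simulate_survival(x, loghr=1.0, censor_rate=0.2, seed=15)
        res, p, labels = dichotomize_and_compare(x, out, bounds=(0.2, 0.8))
        np.testing.assert_array_equal(labels, np.asarray(x) > res.cutoff)

    def test_planted_prognostic_direction(self):
        # hazard increases with x, so the high-expression group fares worse
        rng = np.random.default_rng(16)
        x = rng.normal(size=120)
        out = simulate_survival(x, loghr=1.2, censor_rate=0.2, seed=17)
        res, p, labels = dichotomize_and_compare(x, out)
        assert p < 0.01
        high_events = np.mean([o.event for o, keep in zip(out, labels) if keep])
        low_events = np.mean([o.event for o, keep in zip(out, labels) if not keep])
        assert high_events > low_events

    def test_null_adjusted_p_calibration(self):
        rej = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=60)
            out = simulate_survival(
                rng.normal(size=60), loghr=0.5, censor_rate=0.3, seed=seed + 20_000
            )
            res, _, _ = dichotomize_and_compare(x, out)
            rej += res.p_adj < 0.05
        assert rej / n_seeds <= 0.08
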