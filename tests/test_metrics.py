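"""Validation metrics: RMSE, fit line, LOOCV q^2, delta AUC, rank tests."""

import itertools

import numpy as np
import pytest
import scipy.stats

from mpalss.exceptions import (
    DegenerateInputError,
    InsufficientDataError,
    UndefinedTestError,
)
from mpalss.lss import SamplingScheme, fit_ols
from mpalss.metrics import (
    delta_auc,
    group_comparison,
    holm_adjust,
    loocv,
    r2_and_fit_line,
    rmse,
    validate_equation,
    wilcoxon_matched_pairs,
)
from mpalss.nca import trapezoidal_auc
from mpalss.profiles import GE31, LT31
from mpalss.simulate import simulate_cohort

from conftest import make_profiles_with_auc


class TestRmseAndDelta:
    def test_hand_examples(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmse([3, 4, 5], [1, 2, 3]) == pytest.approx(2.0)
        assert rmse([1, 2, 3], [2, 2, 1]) == pytest.approx(np.sqrt(5 / 3))

    def test_shape_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1])
        with pytest.raises(ValueError):
            rmse([], [])

    def test_delta_examples_and_symmetry(self):
        assert list(delta_auc([50.0], [47.4])) == [pytest.approx(2.6)]
        x, y = np.random.default_rng(0).uniform(20, 80, (2, 30))
        assert np.allclose(delta_auc(x, y), delta_auc(y, x))
        assert np.median(delta_auc(x, x)) == 0.0

    def test_rmse_squared_times_n_equals_sum_of_squared_deltas(self):
        rng = np.random.default_rng(1)
        est, mea = rng.uniform(20, 80, (2, 41))
        assert rmse(est, mea) ** 2 * 41 == pytest.approx(
            float(np.sum(delta_auc(est, mea) ** 2)), rel=1e-12)


class TestFitLine:
    def test_identity_and_sign_blindness(self):
        x = np.array([10, 20, 30, 40, 50.0])
        r2, slope, intercept = r2_and_fit_line(x, x)
        assert (r2, slope, intercept) == (pytest.approx(1.0), pytest.approx(1.0),
                                          pytest.approx(0.0, abs=1e-9))
        r2n, slopen, _ = r2_and_fit_line(-x + 10, x)
        assert r2n == pytest.approx(1.0) and slopen == pytest.approx(-1.0)

    def test_five_point_case_matches_closed_form(self):
        mea = np.array([41.0, 55.0, 38.0, 62.0, 50.0])
        est = np.array([44.0, 51.0, 40.0, 66.0, 47.0])
        n = 5
        sx, sy = mea.sum(), est.sum()
        sxx, sxy = (mea ** 2).sum(), (mea * est).sum()
        syy = (est ** 2).sum()
        slope_cf = (n * sxy - sx * sy) / (n * sxx - sx ** 2)
        intercept_cf = (sy - slope_cf * sx) / n
        r_cf = (n * sxy - sx * sy) / np.sqrt(
            (n * sxx - sx ** 2) * (n * syy - sy ** 2))
        r2, slope, intercept = r2_and_fit_line(est, mea)
        assert slope == pytest.approx(slope_cf, rel=1e-6)
        assert intercept == pytest.approx(intercept_cf, rel=1e-6)
        assert r2 == pytest.approx(r_cf ** 2, rel=1e-6)

    def test_degenerate_inputs(self):
        with pytest.raises(InsufficientDataError):
            r2_and_fit_line([1, 2], [1, 2])
        with pytest.raises(DegenerateInputError):
            r2_and_fit_line([1, 2, 3], [5, 5, 5])


class TestLoocv:
    def test_exactly_linear_data_gives_q2_of_one(self):
        rng = np.random.default_rng(2)
        rows, targets = [], []
        for _ in range(10):
            row = rng.uniform(1, 8, 9)
            rows.append(row)
            targets.append(150.0 + 2.0 * row[2] + 3.0 * row[6])
        profiles = make_profiles_with_auc(rows, targets)
        cv = loocv(profiles, SamplingScheme((1.0, 6.0)))
        assert cv.q2 == pytest.approx(1.0, abs=1e-9)
        assert cv.press == pytest.approx(0.0, abs=1e-6)

    def test_matches_hat_matrix_shortcut(self, cohort100):
        # independent oracle: for OLS, the held-out residual is
        # resid_i / (1 - h_ii) with h the hat matrix of the full fit
        scheme = SamplingScheme((0.0, 1.0, 3.0, 6.0))
        profiles = cohort100[:40]
        cv = loocv(profiles, scheme)
        X = np.column_stack(
            [np.ones(len(profiles))]
            + [[p.conc_at(t) for p in profiles] for t in scheme])
        y = np.array([trapezoidal_auc(p) for p in profiles])
        hat = X @ np.linalg.pinv(X.T @ X) @ X.T
        resid = y - hat @ y
        press_oracle = float(np.sum((resid / (1 - np.diag(hat))) ** 2))
        assert cv.press == pytest.approx(press_oracle, rel=1e-10)

    def test_needs_enough_profiles(self, cohort100):
        with pytest.raises(InsufficientDataError):
            loocv(cohort100[:6], SamplingScheme((0.0, 1.0, 3.0, 6.0)))

    def test_permuted_responses_have_no_predictive_power(self, cohort100):
        # shuffle measured AUCs against the concentrations: q2 near or
        # below zero, never meaningfully positive
        scheme = SamplingScheme((0.0, 1.0, 3.0, 6.0))
        # q2 is invariant to a common location shift of the responses, so a
        # +150 offset keeps the slack-variable construction feasible
        rng = np.random.default_rng(3)
        q2s = []
        for _ in range(20):
            perm = rng.permutation(len(cohort100))
            shuffled = [
                make_profiles_with_auc(
                    [np.array(p.concs_ug_ml)],
                    [trapezoidal_auc(cohort100[j]) + 150.0],
                )[0]
                for p, j in zip(cohort100, perm)
            ]
            q2s.append(loocv(shuffled, scheme).q2)
        assert np.median(q2s) < 0.1

    def test_q2_never_beats_resubstitution_r2(self, config):
        for seed in range(60, 72):
            profiles = simulate_cohort(24, LT31, config, seed=seed)
            scheme = SamplingScheme((0.0, 1.0, 3.0, 6.0))
            fit = fit_ols(profiles, scheme)
            cv = loocv(profiles, scheme)
            assert cv.q2 <= fit.r2 + 1e-12


class TestWilcoxon:
    def test_identical_pairs_are_undefined(self):
        with pytest.raises(UndefinedTestError):
            wilcoxon_matched_pairs([1.0, 2.0, 3.0] * 3, [1.0, 2.0, 3.0] * 3)

    def test_too_few_nonzero_differences(self):
        x = [1.0, 2, 3, 4, 5, 6]
        y = [1.0, 2, 3, 4, 5, 6.5]
        with pytest.raises(InsufficientDataError):
            wilcoxon_matched_pairs(x, y)

    def test_p_invariant_to_adding_a_constant_to_both_members(self):
        rng = np.random.default_rng(4)
        x = rng.normal(5, 2, 30)
        y = x + rng.normal(0.4, 1, 30)
        _, p1 = wilcoxon_matched_pairs(x, y)
        _, p2 = wilcoxon_matched_pairs(x + 17.3, y + 17.3)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_exact_p_at_n8_matches_full_enumeration(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.6, 1.0, 8)
        assert np.unique(np.abs(d)).size == 8 and (d != 0).all()
        x = d + 10.0
        y = np.full(8, 10.0)
        stat, p = wilcoxon_matched_pairs(x, y)
        ranks = scipy.stats.rankdata(np.abs(d))
        w_plus = sum(r for r, v in zip(ranks, d) if v > 0)
        total = ranks.sum()
        dist = np.zeros(int(total) + 1)
        for signs in itertools.product([0, 1], repeat=8):
            dist[int(sum(r for r, s in zip(ranks, signs) if s))] += 1
        dist /= dist.sum()
        cdf = dist[: int(w_plus) + 1].sum()
        sf = dist[int(w_plus):].sum()
        p_enum = min(1.0, 2.0 * min(cdf, sf))
        assert p == pytest.approx(p_enum, rel=1e-12)
        assert stat == min(w_plus, total - w_plus)

    def test_detects_a_consistent_two_unit_shift(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(100):
            y = rng.normal(50, 5, 100)
            x = y + 2.0 + rng.normal(0, 1, 100)
            _, p = wilcoxon_matched_pairs(x, y)
            hits += p < 0.01
        assert hits >= 95


class TestGroupComparison:
    def test_identical_constant_groups(self):
        comp = group_comparison({"a": [3.0] * 5, "b": [3.0] * 5, "c": [3.0] * 4})
        assert comp.h_statistic == 0.0
        assert comp.omnibus_p == 1.0
        assert all(v["adj_p"] == 1.0 for v in comp.pairwise.values())

    def test_holm_hand_example(self):
        adj = holm_adjust([0.01, 0.02, 0.04])
        assert list(adj) == [pytest.approx(0.03), pytest.approx(0.04),
                             pytest.approx(0.04)]

    def test_small_group_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            group_comparison({"a": [1, 2, 3], "b": [1, 2]})

    def test_invariant_to_group_insertion_order(self):
        rng = np.random.default_rng(7)
        g = {k: rng.normal(i, 1, 12) for i, k in enumerate("abc")}
        c1 = group_comparison(g)
        c2 = group_comparison({k: g[k] for k in reversed(list(g))})
        assert c1.omnibus_p == pytest.approx(c2.omnibus_p, rel=1e-12)
        for pair, v in c1.pairwise.items():
            assert c2.adjusted_p(*pair) == pytest.approx(v["adj_p"], rel=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(8)
        g = {k: rng.normal(0, 1, 10) for k in "abcd"}
        comp = group_comparison(g)
        for v in comp.pairwise.values():
            assert v["adj_p"] >= v["raw_p"] - 1e-15


class TestValidateEquation:
    def test_report_is_consistent_with_primitive_metrics(self, ge_cohort):
        from mpalss.lss import equation_registry, predict

        eq = equation_registry()["method_b_ge31"]
        rep = validate_equation(ge_cohort, eq)
        est = predict(eq, ge_cohort)
        mea = np.array([trapezoidal_auc(p) for p in ge_cohort])
        assert rep.rmse == pytest.approx(rmse(est, mea))
        assert rep.delta_median == pytest.approx(float(np.median(delta_auc(est, mea))))
        assert rep.n == len(ge_cohort)
        assert rep.q2 is None  # fixed equation: no refitting q2
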