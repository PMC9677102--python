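"""Intensity parameterization, matrix-exponential likelihood and MLE."""

import numpy as np
import pandas as pd
import pytest

import weightstates as ws
from weightstates.markov import (
    ADJACENT_MASK,
    FittedModel,
    IntensityModel,
    build_q,
    compare,
    crude_initial_rates,
    fit,
    hazard_ratios,
    panel_loglik,
    transition_probability,
)

from conftest import panel_frame


def taylor_expm(A, terms=80):
    """Independent oracle: scaling-and-squaring on the plain Taylor series."""
    A = np.asarray(A, dtype=float)
    s = max(0, int(np.ceil(np.log2(max(np.abs(A).sum(axis=1).max(), 1e-300)))) + 1)
    B = A / 2**s
    out = np.eye(A.shape[0])
    term = np.eye(A.shape[0])
    for k in range(1, terms):
        term = term @ B / k
        out = out + term
    for _ in range(s):
        out = out @ out
    return out


def random_q(rng):
    q = rng.uniform(0.02, 1.0, size=4)
    return ws.reference.tridiagonal_q(*q)


class TestBuildQ:
    def test_null_model_diagonal(self, q_all):
        model = IntensityModel(np.log([0.086, 0.341, 0.257, 0.209]))
        Q = build_q(model)
        assert np.allclose(Q, q_all)
        assert np.allclose(np.diag(Q), [-0.086, -0.598, -0.209])
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-14)

    def test_zero_beta_ignores_covariate(self):
        model = IntensityModel(np.log([0.1, 0.3, 0.2, 0.2]), np.zeros((4, 1)), ("z",))
        for z in (-2.0, 0.0, 3.7):
            assert np.allclose(build_q(model, [z]), build_q(IntensityModel(model.log_q)))

    def test_proportional_effect_on_one_transition(self):
        beta = np.zeros((4, 1))
        beta[0, 0] = np.log(2.0)
        base = IntensityModel(np.log([0.1, 0.3, 0.2, 0.2]))
        model = IntensityModel(base.log_q, beta, ("z",))
        Q0, Q1 = build_q(base), build_q(model, [1.0])
        assert Q1[0, 1] == pytest.approx(2 * Q0[0, 1])
        for (r, s) in [(1, 0), (1, 2), (2, 1)]:
            assert Q1[r, s] == pytest.approx(Q0[r, s])

    def test_null_model_rejects_covariates(self):
        with pytest.raises(ValueError, match="no covariates"):
            build_q(IntensityModel(np.log([0.1, 0.3, 0.2, 0.2])), [1.0])


class TestTransitionProbability:
    def test_zero_intensity_gives_identity(self):
        assert np.allclose(transition_probability(np.zeros((3, 3)), 3.0), np.eye(3))

    def test_reference_one_year_row(self, q_all):
        P = transition_probability(q_all, 1.0)
        assert np.allclose(P[0], [0.929, 0.063, 0.008], atol=5e-3)

    def test_pure_decay_closed_form(self):
        Q = np.array([[-0.5, 0.5, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        P = transition_probability(Q, 1.0)
        assert P[0, 1] == pytest.approx(1 - np.exp(-0.5), abs=1e-12)

    def test_negative_time_rejected(self, q_all):
        with pytest.raises(ValueError):
            transition_probability(q_all, -0.1)

    def test_rows_sum_to_one_entries_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            P = transition_probability(random_q(rng), rng.uniform(0.1, 20))
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert (P >= 0).all() and (P <= 1).all()

    def test_chapman_kolmogorov(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            Q = random_q(rng)
            t, s = rng.uniform(0.1, 5, size=2)
            lhs = transition_probability(Q, t + s)
            rhs = transition_probability(Q, t) @ transition_probability(Q, s)
            assert np.allclose(lhs, rhs, atol=1e-10)

    def test_agrees_with_taylor_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            Q = random_q(rng)
            t = rng.uniform(0.1, 5)
            assert np.allclose(transition_probability(Q, t), taylor_expm(t * Q), atol=1e-8)


class TestPanelLoglik:
    NULL = IntensityModel(np.log([0.086, 0.341, 0.257, 0.209]))

    def test_single_stay_pair(self, q_all):
        ds = panel_frame({"a": [(0, 1), (1, 1)]})
        expected = np.log(transition_probability(q_all, 1.0)[0, 0])
        assert panel_loglik(ds, self.NULL) == pytest.approx(expected)
        assert expected == pytest.approx(-0.0735, abs=5e-4)

    def test_additive_over_children(self):
        one = panel_frame({"a": [(0, 1), (1, 2), (2, 3)]})
        two = panel_frame({"a": [(0, 1), (1, 2), (2, 3)], "b": [(0, 1), (1, 2), (2, 3)]})
        assert panel_loglik(two, self.NULL) == pytest.approx(2 * panel_loglik(one, self.NULL))

    def test_invariant_to_child_order(self, small_cohort):
        ds, _ = small_cohort
        shuffled = ds.df.sample(frac=1.0, random_state=0)
        assert panel_loglik(shuffled, self.NULL) == pytest.approx(panel_loglik(ds, self.NULL))

    def test_invariant_to_splitting_at_observation(self):
        whole = panel_frame({"a": [(0, 1), (1, 2), (2, 3), (3, 2)]})
        split = panel_frame({"a1": [(0, 1), (1, 2)], "a2": [(0, 2), (1, 3), (2, 2)]})
        assert panel_loglik(whole, self.NULL) == pytest.approx(panel_loglik(split, self.NULL))

    def test_observed_jump_through_overweight_is_finite(self, q_all):
        """A 1 -> 3 pair has positive probability over any dt > 0 (the path
        passes through overweight), vanishing as O(dt^2)."""
        lls = []
        for dt in (1.0, 0.5, 0.1, 0.01):
            ds = panel_frame({"a": [(0, 1), (dt, 3)]})
            ll = panel_loglik(ds, self.NULL)
            assert np.isfinite(ll)
            lls.append(ll)
        assert np.all(np.diff(lls) < 0)  # decreasing as dt -> 0
        ratio = [
            transition_probability(q_all, dt)[0, 2] / dt**2 for dt in (0.04, 0.02, 0.01)
        ]
        half = 0.5 * q_all[0, 1] * q_all[1, 2]  # leading Taylor coefficient
        assert ratio[-1] == pytest.approx(half, rel=0.02)

    def test_forbidden_pair_under_degenerate_q_is_minus_inf(self):
        # q23 underflows to exactly 0: an observed 2 -> 3 pair is impossible
        degenerate = IntensityModel(np.array([np.log(0.1), np.log(0.3), -800.0, np.log(0.2)]))
        ds = panel_frame({"a": [(0, 2), (1, 3)]})
        assert panel_loglik(ds, degenerate) == -np.inf


class TestFit:
    def test_recovers_generating_intensities(self, full_cohort, q_all):
        ds, truth = full_cohort
        fm = fit(ds)
        tab = fm.intensity_table().set_index("transition")
        for (r, s), key in zip(
            [(0, 1), (1, 0), (1, 2), (2, 1)], ["1->2", "2->1", "2->3", "3->2"]
        ):
            row = tab.loc[key]
            assert row["lo"] <= q_all[r, s] <= row["hi"]
        # overweight exit rate recovered: q21 close to truth
        assert tab.loc["2->1", "q"] == pytest.approx(q_all[1, 0], abs=0.05)

    def test_deterministic_and_stable_to_start_perturbation(self, small_cohort):
        ds, _ = small_cohort
        fm1 = fit(ds)
        start = IntensityModel(fm1.model.log_q + np.log(1.5), mask=ADJACENT_MASK)
        fm2 = fit(ds, start=start)
        assert np.allclose(fm1.model.log_q, fm2.model.log_q, atol=1e-4)
        assert fm1.loglik == pytest.approx(fm2.loglik, abs=1e-6)

    def test_aic_definition(self, small_cohort):
        ds, _ = small_cohort
        fm = fit(ds)
        assert fm.aic == pytest.approx(-2 * fm.loglik + 2 * fm.n_params)
        assert fm.n_params == 4

    def test_covariance_symmetric_psd(self, small_cohort):
        ds, _ = small_cohort
        fm = fit(ds)
        assert np.allclose(fm.cov, fm.cov.T)
        assert np.linalg.eigvalsh(fm.cov).min() > -1e-10

    def test_no_events_pins_boundary(self):
        ds = panel_frame({f"c{i}": [(0, 1), (1, 1), (2, 2), (3, 1)] for i in range(20)})
        fm = fit(ds)
        assert (2, 3) in fm.boundary and (3, 2) in fm.boundary
        tab = fm.intensity_table().set_index("transition")
        assert tab.loc["2->3", "q"] < 1e-2

    def test_crude_rates_are_deterministic_start(self, small_cohort):
        ds, _ = small_cohort
        r1 = crude_initial_rates(ds)
        r2 = crude_initial_rates(ds)
        assert np.array_equal(r1, r2)
        assert (r1 > 0).all()


class TestCovariates:
    def test_hazard_ratio_point_and_ci(self):
        model = IntensityModel(np.log([0.1, 0.3, 0.2, 0.2]), np.zeros((4, 1)), ("z",))
        fm = FittedModel(
            model=model,
            theta=model.pack(),
            cov=np.diag([0.01] * 8),
            loglik=-100.0,
            converged=True,
            n_iter=1,
        )
        hr = hazard_ratios(fm)
        assert np.allclose(hr["hr"], 1.0)
        assert np.allclose(hr["lo"], np.exp(-1.96 * 0.1), atol=1e-6)
        assert np.allclose(hr["hi"], np.exp(1.96 * 0.1), atol=1e-6)

    def test_hazard_ratio_of_log2_beta(self):
        model = IntensityModel(
            np.log([0.1, 0.3, 0.2, 0.2]), np.full((4, 1), np.log(2.0)), ("z",)
        )
        fm = FittedModel(model, model.pack(), np.eye(8) * 0.01, -1.0, True, 1)
        assert np.allclose(hazard_ratios(fm)["hr"], 2.0)

    def test_null_model_has_no_hazard_ratios(self, small_cohort):
        ds, _ = small_cohort
        with pytest.raises(ValueError, match="no covariate"):
            hazard_ratios(fit(ds))

    def test_sex_effect_recovery(self):
        """Boys' 1->2 intensity 1.6x girls': the fitted HR covers 1.6."""
        beta = np.array([np.log(1.6), 0.0, 0.0, 0.0])
        cfg = ws.SimulationConfig(
            n_children=1500, covariate_effects={"male": beta}, seed=33
        )
        ds, _ = ws.generate_cohort(cfg)
        fm = fit(ds, covariate="male")
        hr = hazard_ratios(fm).set_index("transition")
        assert hr.loc["1->2", "lo"] < 1.6 < hr.loc["1->2", "hi"]
        assert hr.loc["1->2", "hr"] == pytest.approx(1.6, abs=0.45)


class TestCompare:
    def test_self_comparison_is_null(self, small_cohort):
        ds, _ = small_cohort
        fm = fit(ds)
        res = compare(fm, fm)
        assert res["lrt"] == pytest.approx(0.0, abs=1e-9)
        assert res["p"] == 1.0

    def test_nested_fit_improves_loglik(self, small_cohort):
        ds, _ = small_cohort
        m0 = fit(ds)
        m1 = fit(ds, covariate="male")
        res = compare(m0, m1)
        assert res["df"] == 4
        assert res["lrt"] >= 0
        assert 0 <= res["p"] <= 1

    def test_wrong_nesting_raises(self, small_cohort):
        ds, _ = small_cohort
        m0 = fit(ds)
        worse = FittedModel(m0.model, m0.theta, m0.cov, m0.loglik - 5.0, True, 1)
        with pytest.raises(ValueError, match="lower likelihood"):
            compare(m0, worse)
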