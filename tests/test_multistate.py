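"""Generator construction, transition probabilities, panel likelihood
(against independent oracles) and maximum-likelihood fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from growthmsm.multistate import (
    MarkovMultiState,
    MSMParams,
    build_generator,
    hazard_ratios,
    intensity_summary,
    interval_probability,
    panel_loglik,
    transition_probability,
)
from growthmsm.synthetic import CohortConfig, DropoutModel, panel_from_cohort, simulate_cohort


def params_from_rates(q12, q13, q21, q23, beta=None, covs=None):
    lq = np.log(np.maximum(np.array([q12, q13, q21, q23], float), 1e-300))
    lq[lq == np.log(1e-300)] = -np.inf
    return MSMParams(log_q0=lq, beta=beta or {}, covariates=covs or {})


class TestGenerator:
    def test_zero_intensities_zero_generator(self):
        p = params_from_rates([0] * 3, [0] * 3, [0] * 3, [0] * 3)
        assert np.allclose(build_generator(p, None, 0), 0.0)

    def test_paper_scale_entry(self):
        p = params_from_rates([0.0372] * 3, [0] * 3, [0] * 3, [0] * 3)
        Q = build_generator(p, None, 0)
        assert Q[0, 1] == pytest.approx(0.0372)
        assert Q[0, 0] == pytest.approx(-0.0372)

    def test_proportional_covariate_doubles_single_entry(self):
        base = params_from_rates([0.02] * 3, [0.01] * 3, [0.1] * 3, [0.03] * 3)
        prop = params_from_rates([0.02] * 3, [0.01] * 3, [0.1] * 3, [0.03] * 3,
                                 beta={0: np.array([np.log(2)])}, covs={0: ["x"]})
        Q0 = build_generator(base, None, 1)
        Q1 = build_generator(prop, np.array([1.0]), 1)
        assert Q1[0, 1] == pytest.approx(2 * Q0[0, 1])
        assert Q1[1, 0] == pytest.approx(Q0[1, 0])
        assert Q1[1, 2] == pytest.approx(Q0[1, 2])

    def test_rows_sum_to_zero(self, paper_scale_params):
        for b in range(3):
            Q = build_generator(paper_scale_params, None, b)
            assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-10)
            assert np.allclose(Q[2], 0.0)


class TestTransitionProbability:
    def test_dt_zero_identity(self, paper_scale_params):
        Q = build_generator(paper_scale_params, None, 0)
        assert np.allclose(transition_probability(Q, 0.0), np.eye(3))

    def test_two_state_collapse_closed_form(self):
        a = 0.07
        p = params_from_rates([a] * 3, [0] * 3, [0] * 3, [0] * 3)
        Q = build_generator(p, None, 0)
        for dt in (0.5, 2.0, 10.0):
            P = transition_probability(Q, dt)
            assert P[0, 0] == pytest.approx(np.exp(-a * dt), rel=1e-12)

    def test_matches_ode_oracle(self):
        rng = np.random.default_rng(3)
        q = rng.uniform(0.01, 0.3, size=4)
        p = params_from_rates(*[[v] * 3 for v in q])
        Q = build_generator(p, None, 0)
        dt = 2.5
        sol = solve_ivp(lambda t, y: (y.reshape(3, 3) @ Q).ravel(),
                        (0, dt), np.eye(3).ravel(), rtol=1e-10, atol=1e-12)
        P_ode = sol.y[:, -1].reshape(3, 3)
        assert np.allclose(transition_probability(Q, dt), P_ode, atol=1e-8)

    def test_rows_sum_to_one(self, paper_scale_params):
        Q = build_generator(paper_scale_params, None, 2)
        P = transition_probability(Q, 17.0)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.all((P >= 0) & (P <= 1))

    def test_chapman_kolmogorov_within_band(self, paper_scale_params):
        Q = build_generator(paper_scale_params, None, 1)
        P1 = transition_probability(Q, 1.5)
        P2 = transition_probability(Q, 2.5)
        P3 = transition_probability(Q, 4.0)
        assert np.allclose(P1 @ P2, P3, atol=1e-8)


class TestIntervalProbability:
    def test_within_band_equals_direct(self, paper_scale_params):
        P1 = interval_probability(paper_scale_params, None, 13.0, 20.0)
        Q = build_generator(paper_scale_params, None, 2)
        assert np.allclose(P1, transition_probability(Q, 7.0), atol=1e-12)

    def test_band_crossing_two_state(self):
        a, b = 0.05, 0.11
        p = params_from_rates([a, b, b], [0] * 3, [0] * 3, [0] * 3)
        P = interval_probability(p, None, 4.0, 8.0)
        assert P[0, 0] == pytest.approx(np.exp(-2 * a) * np.exp(-2 * b), rel=1e-12)

    def test_three_band_crossing_vs_discretization(self, paper_scale_params):
        # fine-grained product oracle at 0.01-month steps
        t0, t1 = 2.0, 40.0
        P_fine = np.eye(3)
        n_steps = int(round((t1 - t0) / 0.01))
        edges = np.linspace(t0, t1, n_steps + 1)
        for lo, hi in zip(edges[:-1], edges[1:]):
            mid = 0.5 * (lo + hi)
            band = 0 if mid < 6 else (1 if mid < 12 else 2)
            Q = build_generator(paper_scale_params, None, band)
            P_fine = P_fine @ expm(Q * (hi - lo))
        P = interval_probability(paper_scale_params, None, t0, t1)
        assert np.allclose(P, P_fine, atol=1e-6)


def brute_force_loglik(panel, params):
    """Independent likelihood implementation: per-interval scipy expm."""
    ll = 0.0
    for _, g in panel.groupby("child_id"):
        g = g.sort_values("age_months")
        recs = g.to_dict("records")
        for a, b in zip(recs[:-1], recs[1:]):
            P = np.eye(3)
            t0, t1 = a["age_months"], b["age_months"]
            cuts = [t0] + [e for e in (6.0, 12.0) if t0 < e < t1] + [t1]
            for lo, hi in zip(cuts[:-1], cuts[1:]):
                band = 0 if hi <= 6 else (1 if hi <= 12 else 2)
                P = P @ expm(build_generator(params, None, band) * (hi - lo))
            r, s = a["state"], b["state"]
            if b.get("obs_type") == "exact_death":
                band = 0 if t1 <= 6 else (1 if t1 <= 12 else 2)
                Qend = build_generator(params, None, band)
                ll += np.log(P[r - 1, 0] * Qend[0, 2] + P[r - 1, 1] * Qend[1, 2])
            else:
                ll += np.log(P[r - 1, s - 1])
    return ll


class TestPanelLoglik:
    def test_zero_generator_constant_states(self):
        p = params_from_rates([0] * 3, [0] * 3, [0] * 3, [0] * 3)
        panel = pd.DataFrame({
            "child_id": [0, 0, 1, 1], "age_months": [1.0, 4.0, 2.0, 9.0],
            "state": [1, 1, 2, 2], "obs_type": ["panel"] * 4})
        assert panel_loglik(panel, p) == pytest.approx(0.0, abs=1e-12)

    def test_two_state_closed_form(self):
        a = 0.08
        p = params_from_rates([a] * 3, [0] * 3, [0] * 3, [0] * 3)
        panel = pd.DataFrame({
            "child_id": [0, 0], "age_months": [0.0, 5.0],
            "state": [1, 1], "obs_type": ["panel"] * 2})
        assert panel_loglik(panel, p) == pytest.approx(-a * 5.0, rel=1e-12)

    def test_matches_brute_force_at_random_points(self, toy_panel):
        rng = np.random.default_rng(12)
        for _ in range(20):
            q = rng.uniform(0.005, 0.25, size=(4, 3))
            p = MSMParams(log_q0=np.log(q))
            ll = panel_loglik(toy_panel, p)
            ll_bf = brute_force_loglik(toy_panel, p)
            assert ll == pytest.approx(ll_bf, abs=1e-8)

    def test_zero_probability_transition_gives_neg_inf(self):
        p = params_from_rates([0] * 3, [0] * 3, [0] * 3, [0] * 3)
        panel = pd.DataFrame({
            "child_id": [0, 0], "age_months": [0.0, 3.0],
            "state": [1, 2], "obs_type": ["panel"] * 2})
        with pytest.warns(UserWarning, match="zero-probability"):
            assert panel_loglik(panel, p) == -np.inf

    def test_exact_death_reduces_to_panel_when_no_deaths(self, toy_panel):
        # with death intensities structurally zero and no death rows, the
        # likelihood only involves the live 2x2 block
        live = toy_panel[toy_panel["state"] != 3]
        live = live[live.groupby("child_id")["age_months"].transform("size") >= 2]
        q = np.array([[0.03] * 3, [1e-300] * 3, [0.12] * 3, [1e-300] * 3])
        p_nodeath = MSMParams(log_q0=np.log(q))
        p_struct = MSMParams(log_q0=np.where(np.log(q) < -600, -np.inf, np.log(q)))
        assert panel_loglik(live, p_struct) == pytest.approx(
            panel_loglik(live, p_nodeath), abs=1e-9)


@pytest.fixture(scope="module")
def fitted_cohort():
    cfg = CohortConfig(seed=202, group_sizes=(250, 250, 250, 250),
                       dropout=DropoutModel(mode="MCAR", rate=0.0))
    coh = simulate_cohort(cfg, mode="state_first")
    panel = panel_from_cohort(coh)
    est = MarkovMultiState().fit(panel)
    return cfg, panel, est


class TestFit:
    def test_recovers_truth_within_wald_intervals(self, fitted_cohort):
        cfg, _, est = fitted_cohort
        truth = np.log([cfg.true_q0[t] for t in [(1, 2), (1, 3), (2, 1), (2, 3)]]).ravel()
        th, se = est.fit_.theta, est.fit_.se
        # at n=1000 nearly all 12 log-intensities should be covered
        covered = np.abs(th - truth) <= 1.96 * se
        assert covered.sum() >= 10

    def test_optimizer_stable_under_perturbed_init(self, fitted_cohort):
        _, panel, est = fitted_cohort
        rng = np.random.default_rng(5)
        init = est.fit_.theta + rng.uniform(-0.5, 0.5, est.fit_.theta.shape)
        est2 = MarkovMultiState().fit(panel, init=init)
        assert est2.loglik_ == pytest.approx(est.loglik_, abs=1e-4)

    def test_nested_model_loglik_ordering(self, fitted_cohort):
        _, panel, est = fitted_cohort
        panel2 = panel.copy()
        panel2["x"] = (panel2["child_id"] % 2).astype(float)
        full = MarkovMultiState(covariates={(1, 2): ["x"]}).fit(panel2)
        assert full.loglik_ >= est.loglik_ - 1e-6

    def test_unobserved_transitions_fixed_at_zero(self):
        # no deaths in the data -> death intensities structurally zero
        rows = []
        for cid in range(30):
            states = [1, 2, 1, 2]
            for j, t in enumerate([0.0, 6.0, 12.0, 24.0]):
                rows.append({"child_id": cid, "age_months": t,
                             "state": states[j], "obs_type": "panel"})
        est = MarkovMultiState().fit(pd.DataFrame(rows))
        assert np.isneginf(est.params_.log_q0[1]).all()
        assert np.isneginf(est.params_.log_q0[3]).all()
        assert np.isfinite(est.params_.log_q0[0]).all()

    def test_covariate_hazard_ratio_recovery(self):
        # true exp(beta) = 3.0 on healthy->malnourished for one group
        from growthmsm.synthetic import CohortConfig, DropoutModel, simulate_cohort
        cfg = CohortConfig(seed=303, group_sizes=(0, 600, 600, 0),
                          true_beta={(1, 2): {"group_HIL": np.log(3.0)}},
                          dropout=DropoutModel(mode="MCAR", rate=0.0))
        coh = simulate_cohort(cfg, mode="state_first")
        v = coh.visits
        v["group_HIL"] = (v["group"] == "HIL").astype(float)
        panel = v[v["observed"] | (v["obs_type"] == "exact_death")][
            ["child_id", "age_months", "state", "obs_type", "group_HIL"]]
        est = MarkovMultiState(covariates={(1, 2): ["group_HIL"]}).fit(panel)
        row = est.hazard_ratios().iloc[0]
        assert row["lower"] < 3.0 < row["upper"]
        assert row["aHR"] == pytest.approx(3.0, rel=0.25)

    def test_covariance_symmetric_psd(self, fitted_cohort):
        _, _, est = fitted_cohort
        C = est.covariance_
        assert np.allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() > 0


class TestSummaries:
    def _fit_with_beta(self, beta, se_target=0.1):
        q = np.full((4, 3), 0.02)
        params = MSMParams(log_q0=np.log(q), beta={0: np.array([beta])},
                           covariates={0: ["x"]})
        theta = np.concatenate([np.log(q).ravel(), [beta]])
        names = [f"logq_{t}_b{b}" for t in ("12", "13", "21", "23") for b in range(3)]
        names += ["beta_12_x"]
        cov = np.eye(13) * se_target ** 2
        from growthmsm.multistate import MSMFit
        return MSMFit(params=params, theta=theta, param_names=names, loglik=0.0,
                      covariance=cov, converged=True, n_iter=1, n_children=1)

    def test_null_beta_gives_unit_hr(self):
        fit = self._fit_with_beta(0.0)
        hr = hazard_ratios(fit)
        row = hr.iloc[0]
        assert row["aHR"] == pytest.approx(1.0)
        assert row["lower"] < 1 < row["upper"]

    def test_hr_closed_form(self):
        fit = self._fit_with_beta(np.log(2.0), se_target=0.1)
        row = hazard_ratios(fit).iloc[0]
        assert row["lower"] == pytest.approx(1.644, abs=2e-3)
        assert row["upper"] == pytest.approx(2.433, abs=2e-3)

    def test_recoded_binary_flips_hr(self, fitted_cohort):
        _, panel, _ = fitted_cohort
        panel = panel.copy()
        panel["x"] = (panel["child_id"] % 2).astype(float)
        hr1 = MarkovMultiState(covariates={(1, 2): ["x"]}).fit(panel).hazard_ratios()
        panel["x"] = 1.0 - panel["x"]
        hr2 = MarkovMultiState(covariates={(1, 2): ["x"]}).fit(panel).hazard_ratios()
        assert hr1["aHR"].iloc[0] == pytest.approx(1 / hr2["aHR"].iloc[0], rel=1e-3)

    def test_intensity_scaling_and_ci(self):
        # q = 0.0372/month is 37.2 per 1000 person-months; log-scale CI
        q = np.full((4, 3), 0.02)
        q[0, 0] = 0.0372
        params = MSMParams(log_q0=np.log(q), beta={}, covariates={})
        theta = np.log(q).ravel()
        cov = np.zeros((12, 12))
        cov[0, 0] = 0.377 ** 2
        from growthmsm.multistate import MSMFit
        fit = MSMFit(params=params, theta=theta, param_names=["p"] * 12, loglik=0,
                     covariance=cov, converged=True, n_iter=1, n_children=1)
        tab = intensity_summary(fit)
        row = tab[(tab["transition"] == "1->2") & (tab["band"] == "(0,6]")].iloc[0]
        assert row["per1000pm"] == pytest.approx(37.2)
        assert row["lower"] == pytest.approx(17.8, abs=0.2)
        assert row["upper"] == pytest.approx(77.9, abs=0.5)
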