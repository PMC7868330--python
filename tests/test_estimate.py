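"""Constrained EM: likelihood, E/M steps, multi-start fitting, classification."""

import numpy as np
import pytest
from scipy.special import expit

from dcmsim import (
    DesignCondition,
    FitConfig,
    QMatrix,
    assign_item_models,
    build_qmatrix,
    classify,
    em_fit,
    enumerate_profiles,
    generating_parameters,
    make_item_params,
    marginal_loglik,
    probability_table,
    simulate_condition,
    simulate_responses,
)
from dcmsim.estimate import e_step, m_step_item, m_step_structural


def brute_force_loglik(data, table, props):
    """Literal double-loop mixture likelihood (independent oracle)."""
    total = 0.0
    for x in np.asarray(data):
        lik = 0.0
        for c in range(table.shape[1]):
            term = props[c]
            for i, xi in enumerate(x):
                term *= table[i, c] if xi else 1 - table[i, c]
            lik += term
        total += np.log(lik)
    return total


class TestMarginalLoglik:
    def test_hand_computed_single_item(self):
        # one respondent answering one single-attribute item correctly
        q = QMatrix(np.array([[1]]))
        p = [make_item_params([1], "DINA", np.log(0.25 / 0.75),
                              e_param=np.log(0.87 / 0.13) - np.log(0.25 / 0.75))]
        ll = marginal_loglik(np.array([[1]]), p, np.array([0.5, 0.5]), q,
                             np.array(["DINA"]))
        assert ll == pytest.approx(np.log(0.5 * 0.25 + 0.5 * 0.87), abs=1e-10)

    def test_uninformative_items(self):
        q = build_qmatrix(3, 12)
        spec = assign_item_models(q, "DINA")
        p = [make_item_params(row, "DINA", 0.0, e_param=1e-13)
             for row in q.entries]
        data = (np.arange(60) % 2).reshape(5, 12)
        props = np.random.default_rng(0).dirichlet(np.ones(8))
        ll = marginal_loglik(data, p, props, q, spec)
        assert ll == pytest.approx(5 * 12 * np.log(0.5), abs=1e-8)

    def test_agrees_with_brute_force_enumeration(self):
        q = QMatrix(np.array([[1, 0], [0, 1], [1, 1], [1, 1]]))
        spec = np.array(["CRUM", "CRUM", "LCDM", "DINA"])
        params = generating_parameters(q, spec)
        profiles = enumerate_profiles(2)
        table = probability_table(params, q, spec, profiles)
        rng = np.random.default_rng(3)
        data = rng.integers(0, 2, size=(5, 4))
        props = rng.dirichlet(np.ones(4))
        ours = marginal_loglik(data, params, props, q, spec)
        assert ours == pytest.approx(brute_force_loglik(data, table, props),
                                     abs=1e-10)


class TestESten:
    def test_uninformative_posterior_equals_prior(self):
        q = build_qmatrix(3, 12)
        spec = assign_item_models(q, "DINO")
        p = [make_item_params(row, "DINO", 0.3, e_param=1e-13)
             for row in q.entries]
        props = np.random.default_rng(1).dirichlet(np.ones(8))
        data = np.random.default_rng(2).integers(0, 2, (6, 12))
        post = e_step(data, p, props, q, spec)
        assert np.allclose(post, props, atol=1e-10)

    def test_degenerate_prior(self):
        q = build_qmatrix(3, 12)
        spec = assign_item_models(q, "DINA")
        params = generating_parameters(q, spec)
        props = np.zeros(8)
        props[5] = 1.0
        data = np.random.default_rng(2).integers(0, 2, (4, 12))
        post = e_step(data, params, props, q, spec)
        assert post.argmax(axis=1).tolist() == [5, 5, 5, 5]
        assert post.max(axis=1).min() > 0.999

    def test_bayes_rule_two_class_one_item(self):
        q = QMatrix(np.array([[1]]))
        p = [make_item_params([1], "DINA", np.log(0.25 / 0.75),
                              e_param=np.log(0.87 / 0.13) - np.log(0.25 / 0.75))]
        post = e_step(np.array([[1]]), p, np.array([0.5, 0.5]), q,
                      np.array(["DINA"]))
        assert post[0, 1] == pytest.approx(0.87 / (0.25 + 0.87), abs=1e-10)

    def test_rows_normalized(self, dina_bundle_small):
        b = dina_bundle_small
        props = np.full(8, 1 / 8)
        post = e_step(b.responses, b.true_params, props, b.qmatrix, b.model_spec)
        assert np.allclose(post.sum(axis=1), 1.0)


class TestMStep:
    def test_two_group_closed_form(self):
        """Large balanced counts at rates 0.25/0.87 recover the logit params."""
        profiles = enumerate_profiles(3)
        qrow = np.array([1, 1, 0])
        complete = (profiles[:, 0] * profiles[:, 1]).astype(bool)
        trials = np.full(8, 1000.0)
        succ = np.where(complete, 870.0, 250.0)
        p = m_step_item((succ, trials), qrow, "DINA", profiles)
        assert p.intercept == pytest.approx(np.log(0.25 / 0.75), abs=1e-6)
        assert p.e_param == pytest.approx(
            np.log(0.87 / 0.13) - np.log(0.25 / 0.75), abs=1e-6
        )

    def test_flat_success_rate_pins_increment_at_bound(self):
        profiles = enumerate_profiles(3)
        qrow = np.array([1, 0, 1])
        trials = np.full(8, 500.0)
        succ = np.full(8, 200.0)  # rate 0.4 in every class
        p = m_step_item((succ, trials), qrow, "DINO", profiles, eps=1e-4)
        assert p.e_param == pytest.approx(1e-4, abs=1e-6)
        assert p.intercept == pytest.approx(np.log(0.4 / 0.6), abs=1e-3)

    def test_matches_grid_search_oracle(self):
        """Coarse-to-fine grid search over (intercept, e) agrees within 1e-3."""
        profiles = enumerate_profiles(2)
        qrow = np.array([1, 1])
        trials = np.array([40.0, 25.0, 25.0, 60.0])
        succ = np.array([12.0, 8.0, 9.0, 51.0])
        p = m_step_item((succ, trials), qrow, "DINA", profiles)

        def expected_ll(l0, e):
            kern = np.array([l0, l0, l0, l0 + e])
            return float(succ @ kern - trials @ np.log1p(np.exp(kern)))

        best, arg = -np.inf, None
        for l0 in np.arange(-4, 4, 0.01):
            for e in np.arange(0.01, 4, 0.01):
                v = expected_ll(l0, e)
                if v > best:
                    best, arg = v, (l0, e)
        assert p.intercept == pytest.approx(arg[0], abs=1e-2)
        assert p.e_param == pytest.approx(arg[1], abs=1e-2)
        assert expected_ll(p.intercept, p.e_param) >= best - 1e-6

    def test_degenerate_counts_return_warm_start(self):
        profiles = enumerate_profiles(3)
        x0 = np.array([-0.8, 1.5])
        p = m_step_item((np.zeros(8), np.zeros(8)), np.array([1, 1, 0]),
                        "DINA", profiles, x0=x0)
        assert np.allclose(p.values, x0)

    def test_structural_step(self):
        post = np.eye(4)[[0, 0, 1, 3]]
        props = m_step_structural(post)
        assert np.allclose(props, [0.5, 0.25, 0.0, 0.25])
        assert np.allclose(m_step_structural(np.full((5, 4), 0.25)), 0.25)


class TestEMFit:
    def test_ascent_over_true_parameters(self, dina_bundle_small, fast_fit_config):
        b = dina_bundle_small
        fit = em_fit(b, b.qmatrix, b.model_spec, fast_fit_config)
        props_true = np.full(8, 1 / 8)
        ll_true = marginal_loglik(b.responses, b.true_params, props_true,
                                  b.qmatrix, b.model_spec)
        assert fit.loglik >= ll_true

    def test_loglik_trace_monotone(self, dina_bundle_small, fast_fit_config):
        b = dina_bundle_small
        fit = em_fit(b, b.qmatrix, b.model_spec, fast_fit_config)
        assert (np.diff(fit.loglik_trace) >= -1e-7).all()

    def test_constraints_satisfied_on_estimates(self, fast_fit_config):
        cond = DesignCondition(150, 12, 3, 0.5, "LCDMREDUCED")
        b = simulate_condition(cond, np.random.default_rng(21))
        fit = em_fit(b, b.qmatrix, b.model_spec, fast_fit_config)
        for p in fit.item_params:
            for fam, val in zip(p.families, p.values):
                if fam in ("main", "e_param"):
                    assert val >= 1e-4 - 1e-9
            if p.interaction is not None:
                assert all(p.interaction + m >= 1e-4 - 1e-6 for m in p.mains)

    def test_matches_direct_optimizer_small_problem(self, fast_fit_config):
        """EM reaches at least the loglik of a direct parameter-space optimizer."""
        from scipy.optimize import minimize

        q = QMatrix(np.array([[1, 0], [0, 1], [1, 1], [1, 1]]))
        spec = np.array(["DINA"] * 4)
        params = generating_parameters(q, spec)
        profiles = enumerate_profiles(2)
        rng = np.random.default_rng(9)
        prof = profiles[rng.integers(0, 4, size=30)]
        b = simulate_responses(prof, params, q, spec, rng)
        fit = em_fit(b, q, spec, FitConfig(n_starts=10, n_survivors=4, seed=0))

        def neg_ll(theta):
            # same parameter space as the EM: increments in [1e-4, 15],
            # intercepts in [-15, 15]
            ps = [make_item_params(
                      q.entries[i],
                      "DINA",
                      np.clip(theta[2 * i], -15, 15),
                      e_param=np.clip(abs(theta[2 * i + 1]) + 1e-4, 1e-4, 15))
                  for i in range(4)]
            raw = np.concatenate([theta[8:11], [0.0]])
            w = np.exp(raw - raw.max())
            return -marginal_loglik(b.responses, ps, w / w.sum(), q, spec)

        best = np.inf
        for trial in range(8):
            x0 = np.concatenate([rng.normal(0, 1, 8), rng.normal(0, 1, 3)])
            res = minimize(neg_ll, x0, method="Nelder-Mead",
                           options={"maxiter": 4000, "fatol": 1e-10})
            best = min(best, res.fun)
        assert fit.loglik >= -best - 1e-4

    def test_single_attribute_only_design_model_equivalence(self, fast_fit_config):
        """On a test of one-attribute items the four submodels fit identically."""
        q = QMatrix(np.tile(np.eye(3, dtype=int), (2, 1)))
        spec0 = np.array(["DINA"] * 6)
        params = generating_parameters(q, spec0)
        rng = np.random.default_rng(10)
        profiles = enumerate_profiles(3)
        prof = profiles[rng.integers(0, 8, size=400)]
        b = simulate_responses(prof, params, q, spec0, rng)
        logliks = []
        for model in ("DINA", "DINO", "CRUM", "LCDM"):
            spec = np.array([model] * 6)
            fit = em_fit(b.responses, q, spec, fast_fit_config)
            logliks.append(fit.loglik)
        assert max(logliks) - min(logliks) < 1e-6

    def test_binary_data_required(self, q3_12):
        spec = assign_item_models(q3_12, "DINA")
        with pytest.raises(ValueError, match="binary"):
            em_fit(np.full((5, 12), 2), q3_12, spec)


class TestClassify:
    def _fit(self, bundle, cfg):
        return em_fit(bundle, bundle.qmatrix, bundle.model_spec, cfg)

    def test_modal_assignment_and_tiebreak(self):
        profiles = enumerate_profiles(1)
        fake = type("F", (), {})()
        fake.posterior = np.array([[0.1, 0.9], [0.5, 0.5]])
        fake.profiles = profiles
        est, ids, ties = classify(fake)
        assert est[0].tolist() == [1]
        assert ids[1] == 0 and ties[1] and not ties[0]

    def test_noiseless_items_classify_perfectly(self, q3_12, fast_fit_config):
        spec = assign_item_models(q3_12, "DINA")
        params = generating_parameters(q3_12, spec, e_param=12.0,
                                       single_attribute_increment=12.0,
                                       intercept=-6.0)
        rng = np.random.default_rng(14)
        profiles = enumerate_profiles(3)
        prof = profiles[rng.integers(0, 8, size=300)]
        b = simulate_responses(prof, params, q3_12, spec, rng)
        fit = self._fit(b, fast_fit_config)
        est, _, _ = classify(fit)
        from dcmsim import classification_accuracy

        assert classification_accuracy(b.true_profiles, est) > 99.0

    def test_eap_option(self, dina_bundle_small, fast_fit_config):
        fit = self._fit(dina_bundle_small, fast_fit_config)
        est_modal, _, _ = classify(fit, method="modal")
        est_eap, _, _ = classify(fit, method="eap")
        assert est_eap.shape == est_modal.shape
        # the two rules agree for nearly all respondents on clean data
        agree = (est_modal == est_eap).all(axis=1).mean()
        assert agree > 0.9
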