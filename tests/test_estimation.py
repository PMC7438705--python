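"""EM estimation of the latent transition model: likelihood, posteriors,
parameter updates, classification, and nested-model comparison."""

import itertools

import numpy as np
import pytest

from longdcm import (
    AttributeHierarchy,
    InitialPrevalence,
    ItemParams,
    LongitudinalModel,
    ModelSpec,
    QMatrix,
    ResponseData,
    TransitionSet,
    StudyDesign,
    build_design,
    classify,
    default_study_params,
    e_step,
    embed_htdcm,
    enumerate_profiles,
    fit_em,
    kernel_to_transitions,
    loglik,
    lrt,
    m_step,
    simulate_dataset,
    uniform_initial,
)
from longdcm.estimation import _update_item
from longdcm.hierarchy import ProfileSpace
from longdcm.measurement import design_columns


# -- independent oracles ----------------------------------------------------


def brute_loglik(model, y):
    """Sum over all C^T latent trajectories of structural x measurement."""
    pmat = model.prob_matrix()
    delta = model.initial.delta
    taus = model.transitions.matrices
    n, t_len, _ = y.shape
    c = delta.size
    total = 0.0
    for nn in range(n):
        lik = 0.0
        for traj in itertools.product(range(c), repeat=t_len):
            pr = delta[traj[0]]
            for t in range(1, t_len):
                pr *= taus[t - 1][traj[t - 1], traj[t]]
            for t in range(t_len):
                p = pmat[:, traj[t]]
                pr *= np.prod(np.where(y[nn, t] == 1, p, 1 - p))
            lik += pr
        total += np.log(lik)
    return total


def brute_posteriors(model, y):
    """Exact occasion-marginal posteriors by trajectory enumeration."""
    pmat = model.prob_matrix()
    delta = model.initial.delta
    taus = model.transitions.matrices
    n, t_len, _ = y.shape
    c = delta.size
    gamma = np.zeros((n, t_len, c))
    for nn in range(n):
        for traj in itertools.product(range(c), repeat=t_len):
            pr = delta[traj[0]]
            for t in range(1, t_len):
                pr *= taus[t - 1][traj[t - 1], traj[t]]
            for t in range(t_len):
                p = pmat[:, traj[t]]
                pr *= np.prod(np.where(y[nn, t] == 1, p, 1 - p))
            for t in range(t_len):
                gamma[nn, t, traj[t]] += pr
        gamma[nn] /= gamma[nn].sum(axis=1, keepdims=True)
    return gamma


def small_model(seed=0, n_times=3):
    """Linear K=3 model (C=4) with randomized structural parameters."""
    rng = np.random.default_rng(seed)
    h = AttributeHierarchy.linear(3)
    q = QMatrix(np.array([[1, 0, 0], [1, 1, 0], [1, 1, 1]]))
    spec = ModelSpec(hierarchy=h, qmatrix=q, variant="htdcm", n_times=n_times)
    space = spec.space()
    delta = rng.dirichlet(np.ones(4))
    taus = [rng.dirichlet(np.ones(4), size=4) for _ in range(n_times - 1)]
    return LongitudinalModel(
        spec,
        default_study_params(q, h),
        InitialPrevalence(delta),
        TransitionSet(taus),
    )


def random_responses(n, t_len, i_len, seed=0):
    rng = np.random.default_rng(seed)
    return ResponseData(rng.integers(0, 2, size=(n, t_len, i_len)))


# -- likelihood --------------------------------------------------------------


class TestLoglik:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_forward_equals_trajectory_enumeration(self, seed):
        model = small_model(seed)
        data = random_responses(5, 3, 3, seed)
        assert loglik(model, data) == pytest.approx(
            brute_loglik(model, data.y), abs=1e-8
        )

    def test_t1_reduces_to_finite_mixture(self):
        model = small_model(3, n_times=1)
        data = random_responses(20, 1, 3, 3)
        pmat = model.prob_matrix()
        lik = np.zeros(20)
        for c in range(4):
            p = pmat[:, c]
            lik += model.initial.delta[c] * np.prod(
                np.where(data.y[:, 0] == 1, p, 1 - p), axis=1
            )
        assert loglik(model, data) == pytest.approx(np.log(lik).sum(), abs=1e-8)

    def test_single_profile_reduces_to_bernoulli(self):
        # degenerate one-profile space: plain Bernoulli likelihood
        h = AttributeHierarchy.linear(2)
        q = QMatrix(np.array([[1, 0], [1, 1]]))
        spec = ModelSpec(hierarchy=h, qmatrix=q, n_times=2)
        space = ProfileSpace(np.array([[1, 1]], dtype=np.int8), h)
        params = [ItemParams(0.5, {}), ItemParams(-0.3, {})]
        model = LongitudinalModel(
            spec,
            params,
            InitialPrevalence([1.0]),
            TransitionSet([np.ones((1, 1))]),
            _space=space,
        )
        data = random_responses(10, 2, 2, 4)
        from scipy.special import expit

        p = expit([0.5, -0.3])
        expected = np.where(data.y == 1, p, 1 - p)
        assert loglik(model, data) == pytest.approx(np.log(expected).sum(), abs=1e-8)

    def test_no_nan_on_extreme_parameters(self):
        model = small_model(0)
        model.item_params[0] = ItemParams(-40.0, {(0,): 80.0})
        data = random_responses(5, 3, 3, 0)
        assert np.isfinite(loglik(model, data))


class TestEStep:
    @pytest.mark.parametrize("seed", [0, 5])
    def test_matches_enumeration_posteriors(self, seed):
        model = small_model(seed)
        data = random_responses(4, 3, 3, seed)
        post = e_step(model, data)
        assert np.allclose(post.gamma, brute_posteriors(model, data.y), atol=1e-8)

    def test_pair_marginals_are_consistent(self):
        model = small_model(1)
        data = random_responses(6, 3, 3, 1)
        post = e_step(model, data)
        for t, xi in enumerate(post.xi):
            assert np.allclose(xi.sum(axis=(1, 2)), 1.0, atol=1e-10)
            assert np.allclose(xi.sum(axis=1), post.gamma[:, t + 1], atol=1e-8)
            assert np.allclose(xi.sum(axis=2), post.gamma[:, t], atol=1e-8)

    def test_uninformative_items_return_the_prior(self):
        model = small_model(2)
        model.item_params = [ItemParams(0.0, {}) for _ in range(3)]
        data = random_responses(8, 3, 3, 2)
        post = e_step(model, data)
        assert np.allclose(post.gamma[:, 0], model.initial.delta, atol=1e-10)

    def test_near_deterministic_items_recover_the_trajectory(self, linear3):
        design = StudyDesign(
            hierarchy=linear3, design_id="Q3", n_examinees=50, base_seed=9,
            intercept=-12.0, main_effect=24.0, interaction=0.0,
        )
        resp, traj = simulate_dataset(design, 0)
        spec = ModelSpec(hierarchy=linear3, qmatrix=design.qmatrix, n_times=3)
        model = LongitudinalModel(
            spec,
            design.item_params(),
            uniform_initial(design.space()),
            kernel_to_transitions(design),
        )
        post = e_step(model, resp)
        assert (post.gamma.argmax(axis=2) == traj).mean() > 0.99


class TestMStep:
    def test_concentrated_posteriors_recover_frequencies(self, linear3):
        model = small_model(0)
        design = StudyDesign(hierarchy=linear3, design_id="Q2", n_examinees=200, base_seed=3)
        resp, traj = simulate_dataset(design, 0)
        resp = ResponseData(resp.y[:, :, :3])
        post = e_step(model, resp)
        # overwrite with degenerate posteriors at the true trajectory
        post.gamma[:] = 0.0
        for t in range(3):
            post.gamma[np.arange(200), t, traj[:, t]] = 1.0
        for t in range(2):
            post.xi[t][:] = 0.0
            post.xi[t][np.arange(200), traj[:, t], traj[:, t + 1]] = 1.0
        new = m_step(post, resp, model)
        freq = np.bincount(traj[:, 0], minlength=4) / 200
        assert np.allclose(new.initial.delta, freq, atol=1e-10)

    def test_masked_tau_cells_stay_zero(self, linear3):
        q = build_design(linear3, "Q2", 10)
        spec = ModelSpec(hierarchy=linear3, qmatrix=q, n_times=3, forbid_regression=True)
        design = StudyDesign(hierarchy=linear3, design_id="Q2", n_examinees=100, base_seed=5)
        resp, _ = simulate_dataset(design, 0)
        fit = fit_em(resp, spec, n_starts=1, seed=1, max_iter=20, tol=1e-4)
        mask = fit.model.transitions.mask
        assert mask is not None
        for m in fit.model.transitions.matrices:
            assert (m[mask] == 0).all()

    def test_item_update_matches_glm_oracle(self, linear3_space):
        # weighted logistic update vs statsmodels GLM on the same pattern data
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        terms = [(0,), (0, 1), (0, 1, 2)]
        x = design_columns(terms, linear3_space)
        w = rng.uniform(50, 200, size=4)
        truth = np.array([-1.0, 2.0, 1.0, 1.0])
        from scipy.special import expit

        s = w * expit(x @ truth) * rng.uniform(0.9, 1.1, size=4)
        s = np.minimum(s, w * 0.99)
        start = ItemParams(0.0, {t: 0.5 for t in terms})
        ours = _update_item(start, terms, x, s, w, monotone=False, maxiter=500)
        glm = sm.GLM(
            np.column_stack([s, w - s]), x, family=sm.families.Binomial()
        ).fit()
        got = np.r_[ours.intercept, [ours.effects[t] for t in terms]]
        assert np.allclose(got, glm.params, atol=1e-6)


class TestFitEM:
    def test_loglik_trace_is_nondecreasing(self, linear3):
        design = StudyDesign(hierarchy=linear3, design_id="Q2", n_examinees=300, base_seed=2)
        resp, _ = simulate_dataset(design, 0)
        spec = ModelSpec(hierarchy=linear3, qmatrix=design.qmatrix, n_times=3)
        fit = fit_em(resp, spec, n_starts=2, seed=3, max_iter=60, tol=1e-6)
        trace = np.array(fit.loglik_trace)
        assert (np.diff(trace) >= -1e-8).all()

    def test_same_seed_same_fit(self, linear3):
        design = StudyDesign(hierarchy=linear3, design_id="Q2", n_examinees=150, base_seed=4)
        resp, _ = simulate_dataset(design, 0)
        spec = ModelSpec(hierarchy=linear3, qmatrix=design.qmatrix, n_times=3)
        f1 = fit_em(resp, spec, n_starts=2, seed=7, max_iter=40, tol=1e-5)
        f2 = fit_em(resp, spec, n_starts=2, seed=7, max_iter=40, tol=1e-5)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-12)

    def test_dimension_mismatch_errors(self, linear3):
        q = build_design(linear3, "Q2", 10)
        spec = ModelSpec(hierarchy=linear3, qmatrix=q, n_times=3)
        with pytest.raises(ValueError, match="occasions"):
            fit_em(random_responses(5, 2, 10), spec, n_starts=1, seed=0)
        with pytest.raises(ValueError, match="items"):
            fit_em(random_responses(5, 3, 7), spec, n_starts=1, seed=0)

    def test_missing_data_rejected(self):
        y = np.zeros((3, 2, 2))
        y[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            ResponseData(y)

    def test_htdcm_never_beats_tdcm(self, linear3):
        # nested constraint: restricted space + masks can only lose likelihood
        design = StudyDesign(hierarchy=linear3, design_id="Q2", n_examinees=300, base_seed=6)
        resp, _ = simulate_dataset(design, 0)
        hspec = ModelSpec(hierarchy=linear3, qmatrix=design.qmatrix, variant="htdcm", n_times=3)
        hfit = fit_em(resp, hspec, n_starts=2, seed=1, max_iter=80, tol=1e-6)
        tspec = ModelSpec(hierarchy=linear3, qmatrix=design.qmatrix, variant="tdcm", n_times=3)
        tfit = fit_em(
            resp, tspec, n_starts=2, seed=1, max_iter=80, tol=1e-6,
            init=embed_htdcm(hfit.model),
        )
        assert hfit.loglik <= tfit.loglik + 1e-6
        assert hfit.n_free_parameters < tfit.n_free_parameters

    def test_embedded_model_has_identical_likelihood(self, linear3):
        design = StudyDesign(hierarchy=linear3, design_id="Q2", n_examinees=80, base_seed=8)
        resp, _ = simulate_dataset(design, 0)
        spec = ModelSpec(hierarchy=linear3, qmatrix=design.qmatrix, variant="htdcm", n_times=3)
        fit = fit_em(resp, spec, n_starts=1, seed=2, max_iter=30, tol=1e-5)
        assert loglik(embed_htdcm(fit.model), resp) == pytest.approx(
            fit.loglik, abs=1e-6
        )


class TestClassifyAndLRT:
    def test_posterior_rows_sum_to_one(self, linear3):
        design = StudyDesign(hierarchy=linear3, design_id="Q2", n_examinees=50, base_seed=1)
        resp, _ = simulate_dataset(design, 0)
        spec = ModelSpec(hierarchy=linear3, qmatrix=design.qmatrix, n_times=3)
        fit = fit_em(resp, spec, n_starts=1, seed=1, max_iter=20, tol=1e-4)
        est, gamma = classify(fit.model, resp)
        assert np.allclose(gamma.sum(axis=2), 1.0, atol=1e-10)
        assert est.shape == (50, 3)

    def test_near_deterministic_items_classify_exactly(self, linear3):
        design = StudyDesign(
            hierarchy=linear3, design_id="Q3", n_examinees=40, base_seed=2,
            intercept=-12.0, main_effect=24.0, interaction=0.0,
        )
        resp, traj = simulate_dataset(design, 0)
        spec = ModelSpec(hierarchy=linear3, qmatrix=design.qmatrix, n_times=3)
        model = LongitudinalModel(
            spec, design.item_params(), uniform_initial(design.space()),
            kernel_to_transitions(design),
        )
        est, _ = classify(model, resp)
        assert (est == traj).mean() > 0.99

    def test_uninformative_data_classifies_to_prior_mode(self):
        model = small_model(6)
        model.item_params = [ItemParams(0.0, {}) for _ in range(3)]
        data = random_responses(5, 3, 3, 6)
        est, _ = classify(model, data)
        assert (est[:, 0] == int(np.argmax(model.initial.delta))).all()

    def test_lrt_identical_fits_give_zero(self, linear3):
        design = StudyDesign(hierarchy=linear3, design_id="Q2", n_examinees=60, base_seed=3)
        resp, _ = simulate_dataset(design, 0)
        spec = ModelSpec(hierarchy=linear3, qmatrix=design.qmatrix, n_times=3)
        fit = fit_em(resp, spec, n_starts=1, seed=1, max_iter=15, tol=1e-4)
        stat, df, p = lrt(fit, fit)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_lrt_df_matches_free_parameter_counting(self, linear3):
        design = StudyDesign(hierarchy=linear3, design_id="Q2", n_examinees=120, base_seed=4)
        resp, _ = simulate_dataset(design, 0)
        hspec = ModelSpec(hierarchy=linear3, qmatrix=design.qmatrix, variant="htdcm", n_times=3)
        tspec = ModelSpec(hierarchy=linear3, qmatrix=design.qmatrix, variant="tdcm", n_times=3)
        hfit = fit_em(resp, hspec, n_starts=1, seed=1, max_iter=25, tol=1e-4)
        tfit = fit_em(resp, tspec, n_starts=1, seed=1, max_iter=25, tol=1e-4,
                      init=embed_htdcm(hfit.model))
        stat, df, p = lrt(hfit, tfit)
        # independent count: item terms + (C-1) + (T-1)*C*(C-1) per variant
        def count(spec):
            c = spec.space().n_profiles
            items = sum(1 + len(t) for t in spec.item_terms())
            return items + (c - 1) + 2 * c * (c - 1)

        assert df == count(tspec) - count(hspec)
        assert stat >= 0.0 and 0.0 <= p <= 1.0

    def test_lrt_rejects_reversed_nesting(self, linear3):
        design = StudyDesign(hierarchy=linear3, design_id="Q2", n_examinees=60, base_seed=5)
        resp, _ = simulate_dataset(design, 0)
        hspec = ModelSpec(hierarchy=linear3, qmatrix=design.qmatrix, variant="htdcm", n_times=3)
        tspec = ModelSpec(hierarchy=linear3, qmatrix=design.qmatrix, variant="tdcm", n_times=3)
        hfit = fit_em(resp, hspec, n_starts=1, seed=1, max_iter=10, tol=1e-3)
        tfit = fit_em(resp, tspec, n_starts=1, seed=1, max_iter=10, tol=1e-3)
        with pytest.raises(ValueError, match="nested"):
            lrt(tfit, hfit)
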