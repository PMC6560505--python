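import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import logsumexp

import mixvpc as m
from mixvpc.datamodel import (
    Dataset,
    DoseEvent,
    MixtureParameters,
    Observation,
    ResidualSpec,
    SubjectData,
)
from mixvpc import mixture_inference as mi
from mixvpc import structural_models as sm
from tests.conftest import make_subject


# ---------------------------------------------------------------------------
# posterior membership and marginal OFV (pure formulas)

class TestMixturePosterior:
    def test_equal_iofv_returns_prior(self):
        ip = mi.mixture_posterior(np.array([3.3, 3.3]), np.array([0.6, 0.4]))
        assert np.allclose(ip, [0.6, 0.4], atol=1e-14)

    def test_degenerate_prior(self):
        ip = mi.mixture_posterior(np.array([50.0, -20.0]), np.array([1.0, 0.0]))
        assert np.allclose(ip, [1.0, 0.0])

    def test_hand_value_sign_corrected(self):
        # smaller iofv (better fit) must receive the larger probability
        ip = mi.mixture_posterior(np.array([2.0, 4.0]), np.array([0.5, 0.5]))
        assert ip[0] == pytest.approx(1.0 / (1.0 + np.exp(-1.0)), rel=1e-12)
        assert ip[0] > ip[1]

    def test_all_zero_prior_rejected(self):
        with pytest.raises(ValueError):
            mi.mixture_posterior(np.array([1.0, 2.0]), np.array([0.0, 0.0]))

    @given(
        iofv=st.lists(st.floats(-500, 500), min_size=2, max_size=4),
        pmix_raw=st.lists(st.floats(0.01, 1), min_size=2, max_size=4),
        offset=st.floats(-1e6, 1e6),
    )
    def test_simplex_and_offset_invariance(self, iofv, pmix_raw, offset):
        k = min(len(iofv), len(pmix_raw))
        iofv = np.array(iofv[:k])
        pmix = np.array(pmix_raw[:k]) / np.sum(pmix_raw[:k])
        ip = mi.mixture_posterior(iofv, pmix)
        assert np.all(ip >= 0) and ip.sum() == pytest.approx(1.0, abs=1e-12)
        ip_shift = mi.mixture_posterior(iofv + offset, pmix)
        assert np.allclose(ip, ip_shift, atol=1e-10)

    @given(delta=st.floats(0.01, 50.0))
    def test_monotonicity_in_iofv(self, delta):
        base = np.array([10.0, 12.0])
        pmix = np.array([0.5, 0.5])
        ip0 = mi.mixture_posterior(base, pmix)
        ip1 = mi.mixture_posterior(base - np.array([delta, 0.0]), pmix)
        assert ip1[0] > ip0[0]


class TestIndividualOfv:
    def test_single_component_passthrough(self):
        assert mi.individual_ofv(np.array([7.25, 99.0]), np.array([1.0, 0.0])) == pytest.approx(7.25)

    def test_common_value_returned(self):
        assert mi.individual_ofv(np.array([3.0, 3.0]), np.array([0.2, 0.8])) == pytest.approx(3.0)

    def test_hand_value(self):
        got = mi.individual_ofv(np.array([2.0, 4.0]), np.array([0.5, 0.5]))
        want = -2.0 * np.log(0.5 * np.exp(-1.0) + 0.5 * np.exp(-2.0))
        assert got == pytest.approx(want, rel=1e-12)
        assert got == pytest.approx(2.7598, abs=5e-5)

    @given(offset=st.floats(-1e5, 1e5))
    def test_offset_shifts_ofv_by_offset(self, offset):
        iofv = np.array([2.0, 4.0])
        pmix = np.array([0.3, 0.7])
        a = mi.individual_ofv(iofv, pmix)
        b = mi.individual_ofv(iofv + offset, pmix)
        assert b - a == pytest.approx(offset, abs=1e-8)


# ---------------------------------------------------------------------------
# Laplace / quadrature individual likelihoods

def brute_force_iofv(subject, theta_cl, omega, sigma_spec, n_grid=4096):
    """Trapezoidal integration of the exact 1-η marginal likelihood
    (N·log 2π excluded), independent of the Laplace machinery."""
    etas = np.linspace(-8 * np.sqrt(omega), 8 * np.sqrt(omega), n_grid)
    theta = {"ka": np.full(n_grid, 1.0), "CL": theta_cl * np.exp(etas),
             "V": np.full(n_grid, 100.0)}
    pred = sm.predict_1cmt_oral_batch(theta, subject.obs_times, subject.doses)
    var = np.maximum(sigma_spec.variance(pred), 1e-300)
    y = subject.obs_values
    loglik = -0.5 * np.sum(np.log(var) + (y - pred) ** 2 / var, axis=1)
    logprior = -0.5 * np.log(2 * np.pi * omega) - etas**2 / (2 * omega)
    return -2.0 * (logsumexp(loglik + logprior) + np.log(etas[1] - etas[0]))


ADD_SIGMA = ResidualSpec("additive", add_var=0.01)


def _params_1eta(sigma):
    return MixtureParameters([{"CL": 20.0}], {"ka": 1.0, "V": 100.0},
                             np.array([1.0]), {"CL": 0.09}, sigma)


class TestComponentIofv:
    def test_vanishing_omega_recovers_fixed_effects_likelihood(self, toy_subject,
                                                               onecmt_model_1eta):
        params = _params_1eta(ResidualSpec("proportional", prop_var=0.04))
        params.omega = {"CL": 1e-12}
        iofv, mode = mi.component_iofv(toy_subject, params, 0, onecmt_model_1eta)
        pred = sm.predict_1cmt_oral_batch(
            {"ka": np.array([1.0]), "CL": np.array([20.0]), "V": np.array([100.0])},
            toy_subject.obs_times, toy_subject.doses)[0]
        var = 0.04 * pred**2
        direct = np.sum(np.log(var) + (toy_subject.obs_values - pred) ** 2 / var)
        assert iofv == pytest.approx(direct, abs=1e-4)
        assert np.allclose(mode, 0.0, atol=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_laplace_matches_brute_force_on_additive_toys(self, seed,
                                                          onecmt_model_1eta):
        subj = make_subject(str(seed), eta_cl=0.1 * seed - 0.15, seed=seed,
                            sigma=ADD_SIGMA)
        params = _params_1eta(ADD_SIGMA)
        iofv, _ = mi.component_iofv(subj, params, 0, onecmt_model_1eta)
        bf = brute_force_iofv(subj, 20.0, 0.09, ADD_SIGMA)
        assert iofv == pytest.approx(bf, abs=0.05)

    def test_quadrature_matches_brute_force_tightly(self, toy_subject,
                                                    onecmt_model_1eta):
        sigma = ResidualSpec("proportional", prop_var=0.04)
        params = _params_1eta(sigma)
        agq, _ = mi.component_iofv(toy_subject, params, 0, onecmt_model_1eta,
                                   mi.LikelihoodSettings(method="agq", agq_nodes=21))
        bf = brute_force_iofv(toy_subject, 20.0, 0.09, sigma)
        assert agq == pytest.approx(bf, abs=1e-3)

    def test_laplace_close_to_quadrature(self, toy_subject, onecmt_model_1eta):
        params = _params_1eta(ResidualSpec("proportional", prop_var=0.04))
        lap, _ = mi.component_iofv(toy_subject, params, 0, onecmt_model_1eta)
        agq, _ = mi.component_iofv(toy_subject, params, 0, onecmt_model_1eta,
                                   mi.LikelihoodSettings(method="agq", agq_nodes=21))
        assert abs(lap - agq) < 0.1

    def test_quadrature_converges_with_node_count(self, toy_subject,
                                                  onecmt_model_1eta):
        sigma = ResidualSpec("proportional", prop_var=0.04)
        params = _params_1eta(sigma)
        bf = brute_force_iofv(toy_subject, 20.0, 0.09, sigma)
        errs = []
        for nodes in (3, 7, 15, 31):
            agq, _ = mi.component_iofv(toy_subject, params, 0, onecmt_model_1eta,
                                       mi.LikelihoodSettings(method="agq", agq_nodes=nodes))
            errs.append(abs(agq - bf))
        assert errs[-1] <= errs[0]
        assert errs[-1] < 1e-3

    def test_identical_components_give_identical_iofv(self, toy_subject):
        model = mi.ModelSpec("onecmt-oral", "mixture", "CL", ("CL",))
        params = MixtureParameters(
            [{"CL": 25.0}, {"CL": 25.0}], {"ka": 1.0, "V": 100.0},
            np.array([0.5, 0.5]), {"CL": 0.09},
            ResidualSpec("proportional", prop_var=0.04))
        i0, _ = mi.component_iofv(toy_subject, params, 0, model)
        i1, _ = mi.component_iofv(toy_subject, params, 1, model)
        assert abs(i0 - i1) < 1e-10

    def test_all_missing_observations_rejected(self, onecmt_model_1eta):
        subj = SubjectData("x", [DoseEvent(0, 100)],
                           [Observation(1.0, np.nan, missing=True)])
        with pytest.raises(ValueError):
            mi.component_iofv(subj, _params_1eta(ADD_SIGMA), 0, onecmt_model_1eta)


# ---------------------------------------------------------------------------
# evaluation (MAXEVAL=0 analog)

@pytest.fixture(scope="module")
def small_mixture():
    spec = m.scenario_preset("linear-70-30")
    spec.n_subjects = 40
    ds, truth = m.simulate_dataset(spec, 5)
    model = mi.ModelSpec("onecmt-oral", "mixture", "CL", ("ka", "CL", "V"))
    return spec, ds, truth, model


class TestEvaluate:
    def test_degenerate_pmix_forces_component_one(self, small_mixture):
        spec, ds, _, model = small_mixture
        params = spec.true_params.copy()
        params.pmix = np.array([1.0, 0.0])
        recs = mi.evaluate(ds, params, model)
        assert all(np.allclose(r.ip, [1.0, 0.0]) and r.mixest == 1 for r in recs)

    def test_subject_order_independence(self, small_mixture):
        spec, ds, _, model = small_mixture
        shuffled = Dataset(list(reversed(ds.subjects)), ds.design_label)
        a = {r.id: r for r in mi.evaluate(ds, spec.true_params, model)}
        b = {r.id: r for r in mi.evaluate(shuffled, spec.true_params, model)}
        for sid in a:
            assert np.allclose(a[sid].ip, b[sid].ip, atol=1e-12)
            assert np.allclose(a[sid].iofv, b[sid].iofv, atol=1e-9)

    def test_true_parameters_classify_well(self, small_mixture):
        spec, ds, truth, model = small_mixture
        recs = mi.evaluate(ds, spec.true_params, model)
        ip1 = np.array([r.ip[0] for r in recs])
        tk = np.array([truth.component[r.id] for r in recs])
        assert ip1[tk == 1].mean() > 0.9
        assert ip1[tk == 2].mean() < 0.1

    def test_records_carry_consistent_il_and_mixest(self, small_mixture):
        spec, ds, _, model = small_mixture
        for r in mi.evaluate(ds, spec.true_params, model):
            assert r.il.max() == pytest.approx(1.0)
            ratios = np.exp(-(r.iofv - r.iofv.min()) / 2.0)
            assert np.allclose(r.il, ratios, rtol=1e-10)
            assert r.mixest == int(np.argmax(r.ip)) + 1
            assert r.mixest == int(np.argmin(r.iofv - 2 * np.log(
                np.maximum(spec.true_params.pmix, 1e-300)))) + 1


# ---------------------------------------------------------------------------
# maximum-likelihood fitting

class TestFit:
    def test_three_subject_fit_matches_grid_search_oracle(self, onecmt_model_1eta):
        # one free parameter (typical CL), everything else fixed: the fitted
        # OFV must match an exhaustive grid + trapezoid-quadrature maximum.
        # Additive error keeps the Laplace approximation itself essentially
        # exact, so the comparison isolates the optimizer and the likelihood
        # implementation.
        sigma = ADD_SIGMA
        subjects = [make_subject(str(i), eta, seed=i, sigma=sigma)
                    for i, eta in enumerate((-0.25, 0.05, 0.3))]
        ds = Dataset(subjects)
        init = MixtureParameters([{}], {"ka": 1.0, "V": 100.0, "CL": 25.0},
                                 np.array([1.0]), {"CL": 0.09}, sigma)
        fr = mi.fit(ds, onecmt_model_1eta, mi.LikelihoodSettings(n_starts=1),
                    init=init, fix=("theta:ka", "theta:V", "omega:CL", "sigma:add"))

        def total_bf(theta_cl):
            return sum(brute_force_iofv(s, theta_cl, 0.09, sigma) for s in subjects)

        grid = np.linspace(10.0, 40.0, 61)
        best_bf, best_cl = np.inf, None
        for _ in range(5):  # refine to ~1e-4 relative
            vals = [total_bf(c) for c in grid]
            j = int(np.argmin(vals))
            best_bf, best_cl = vals[j], grid[j]
            lo, hi = grid[max(j - 1, 0)], grid[min(j + 1, len(grid) - 1)]
            grid = np.linspace(lo, hi, 41)
        assert fr.ofv == pytest.approx(best_bf, abs=0.1)
        assert fr.params.theta_shared["CL"] == pytest.approx(best_cl, rel=0.02)

    def test_equal_component_data_gains_nothing_from_mixture(self):
        spec = m.scenario_preset("linear-70-30")
        spec.n_subjects = 30
        spec.true_params.theta_component = [{"CL": 20.0}, {"CL": 20.0}]
        ds, _ = m.simulate_dataset(spec, 21)
        settings = mi.LikelihoodSettings(n_starts=1)
        mix_model = mi.ModelSpec("onecmt-oral", "mixture", "CL", ("ka", "CL", "V"))
        nm_model = mi.ModelSpec("onecmt-oral", "nonmixture", "CL", ("ka", "CL", "V"),
                                n_components=1)
        fr_mix = mi.fit(ds, mix_model, settings, init=spec.true_params.copy(), seed=1)
        fr_nm = mi.fit(ds, nm_model, settings, seed=1)
        assert fr_mix.ofv <= fr_nm.ofv + 0.01

    def test_evaluate_at_optimum_reproduces_fit_records(self):
        spec = m.scenario_preset("linear-70-30")
        spec.n_subjects = 40
        ds, _ = m.simulate_dataset(spec, 5)
        model = mi.ModelSpec("onecmt-oral", "mixture", "CL", ("ka", "CL", "V"))
        fr = mi.fit(ds, model, mi.LikelihoodSettings(n_starts=1),
                    init=spec.true_params.copy(), seed=1)
        recs = mi.evaluate(ds, fr.params, model)
        for a, b in zip(fr.records, recs):
            assert np.allclose(a.ip, b.ip, atol=1e-8)

    def test_parameter_recovery_over_replicated_studies(self):
        # repeated simulation + estimation: the mixing-proportion estimator
        # tracks each dataset's realized membership fraction with no
        # systematic offset (pairing against the realized fraction removes
        # the shared binomial draw noise), and the component clearances are
        # recovered within 10%
        spec = m.scenario_preset("linear-70-30")
        spec.n_subjects = 250
        model = mi.ModelSpec("onecmt-oral", "mixture", "CL", ("ka", "CL", "V"))
        settings = mi.LikelihoodSettings(n_starts=1)
        diffs, pmix_hat, cl1_hat, cl2_hat = [], [], [], []
        for seed in range(10):
            ds, truth = m.simulate_dataset(spec, 1000 + seed)
            realized = np.mean([k == 1 for k in truth.component.values()])
            fr = mi.fit(ds, model, settings, init=spec.true_params.copy(), seed=1)
            diffs.append(float(fr.params.pmix[0]) - realized)
            pmix_hat.append(float(fr.params.pmix[0]))
            cl1_hat.append(fr.params.theta_component[0]["CL"])
            cl2_hat.append(fr.params.theta_component[1]["CL"])
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) <= 3 * max(se, 1e-3)
        assert 0.66 <= np.mean(pmix_hat) <= 0.78
        assert np.mean(cl1_hat) == pytest.approx(20.0, rel=0.10)
        assert np.mean(cl2_hat) == pytest.approx(80.0, rel=0.10)

    def test_empty_dataset_rejected(self, onecmt_model_1eta):
        with pytest.raises(ValueError):
            mi.fit(Dataset([]), onecmt_model_1eta)

    def test_covariate_variant_requires_covariate_column(self):
        subjects = [make_subject("1", 0.0, seed=1), make_subject("2", 0.1, seed=2)]
        ds = Dataset(subjects)
        model = mi.ModelSpec("onecmt-oral", "covariate", "CL", ("CL",), n_components=1)
        with pytest.raises(ValueError, match="COV"):
            mi.fit(ds, model, mi.LikelihoodSettings(n_starts=1))
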