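import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal

from desmopk import dataset_io as dio
from desmopk import foce
from desmopk import popmodel as pm


# ---------------------------------------------------------------------------
# toy constructors
# ---------------------------------------------------------------------------

def linear_problems(rng, n_subj=6, n_obs=4, theta=1.5, omega=0.4, sigma=0.3):
    """y_ij = theta + eta_i + eps_ij; FOCE is exact here."""
    probs, data = [], []
    for i in range(n_subj):
        y = theta + rng.normal(0, np.sqrt(omega)) + rng.normal(0, sigma, n_obs)
        data.append(y)

        def predict(eta_batch, th=theta, n=n_obs):
            eta = (eta_batch[:, [0]] if eta_batch.shape[1]
                   else np.zeros((eta_batch.shape[0], 1)))
            return th + eta * np.ones((1, n))

        probs.append(foce.SubjectProblem(i, y, predict))
    return probs, data


def onecpt_model(cl=20.0, v1=15.0, iiv_cl=0.1, iiv_v1=0.2, sigma=0.2,
                 bw_on_cl=None):
    effects = []
    if bw_on_cl is not None:
        effects.append(pm.CovariateEffect("CL", "BW", bw_on_cl, 10.0))
    return pm.PopulationModel(
        structural="one_compartment_bolus",
        theta={"CL": cl, "V1": v1},
        iiv={"CL": iiv_cl, "V1": iiv_v1},
        sigma=sigma,
        covariate_effects=effects,
    )


def onecpt_dataset(model, n_subj=16, seed=0, bw=None,
                   times=(0.1, 0.25, 0.5, 1.0, 1.5, 2.0), dose=1.0e6):
    rng = np.random.default_rng(seed)
    cohort = pd.DataFrame({"id": [f"s{i}" for i in range(n_subj)]})
    if bw is not None:
        cohort["BW"] = bw
    ds, etas = pm.simulate_population(model, cohort, np.asarray(times), dose,
                                      rng=rng, censor="none",
                                      predose_record=False)
    return dio.log_transform(ds), etas


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

class TestConditionalObjective:
    def test_exact_on_linear_gaussian_model(self):
        theta, omega, sigma = 1.5, 0.4, 0.3
        probs, data = linear_problems(np.random.default_rng(0))
        ofv, _ = foce.foce_objective(probs, np.array([[omega]]), sigma)
        exact = 0.0
        for y in data:
            n = len(y)
            V = sigma**2 * np.eye(n) + omega * np.ones((n, n))
            exact += -2.0 * multivariate_normal.logpdf(
                y, mean=theta * np.ones(n), cov=V)
        assert ofv == pytest.approx(exact, abs=1e-8)

    def test_omega_zero_collapses_to_fixed_effects_residual_model(self):
        probs, data = linear_problems(np.random.default_rng(1), omega=0.0)
        sigma = 0.3
        ofv, modes = foce.foce_objective(probs, np.zeros((0, 0)), sigma)
        expect = sum(
            len(y) * np.log(2 * np.pi * sigma**2)
            + np.sum((y - 1.5) ** 2) / sigma**2
            for y in data)
        assert ofv == pytest.approx(expect, rel=1e-12)
        assert all(len(m) == 0 for m in modes.values())

    def test_matches_adaptive_gauss_hermite_on_nonlinear_toy(self):
        """One-eta exponential-decay toy: pred = logA - k exp(eta) t."""
        rng = np.random.default_rng(5)
        logA, k, om_sd, sigma = np.log(800.0), 0.7, 0.5, 0.2
        t = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
        probs, ys = [], []
        for i in range(8):
            eta = rng.normal(0, om_sd)
            y = logA - k * np.exp(eta) * t + rng.normal(0, sigma, len(t))
            ys.append(y)

            def predict(eb, tt=t):
                return logA - k * np.exp(eb[:, [0]]) * tt[None, :]

            probs.append(foce.SubjectProblem(i, y, predict))
        ofv, _ = foce.foce_objective(probs, np.array([[om_sd**2]]), sigma)

        x, w = np.polynomial.hermite.hermgauss(64)
        oracle = 0.0
        for y in ys:
            def nlp(eta):
                f = logA - k * np.exp(eta) * t
                return (0.5 * np.sum((y - f) ** 2) / sigma**2
                        + 0.5 * eta**2 / om_sd**2)
            mu = minimize_scalar(nlp).x
            h = (nlp(mu + 1e-4) - 2 * nlp(mu) + nlp(mu - 1e-4)) / 1e-8
            s = 1.0 / np.sqrt(h)
            const = (2 * np.pi * sigma**2) ** (-len(y) / 2) / np.sqrt(
                2 * np.pi * om_sd**2)
            nodes = mu + np.sqrt(2.0) * s * x
            vals = np.array([np.exp(-nlp(e) + xx**2)
                             for e, xx in zip(nodes, x)])
            L = const * np.sqrt(2.0) * s * float(w @ vals)
            oracle += -2.0 * np.log(L)
        assert ofv == pytest.approx(oracle, abs=0.1)


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

class TestFit:
    def test_noise_free_self_consistency(self):
        """Noise-free data, IIV and sigma estimation disabled: the fit walks
        the fixed effects back to the generating values."""
        gen = onecpt_model(iiv_cl=0.0, iiv_v1=0.0, bw_on_cl=0.75)
        gen.iiv_fixed = {"CL", "V1"}
        noise_free = gen.copy()
        noise_free.sigma = 1e-12
        lds, _ = onecpt_dataset(noise_free, n_subj=6, seed=2,
                                bw=np.array([2.0, 5.0, 8.0, 12.0, 20.0, 40.0]))
        start = gen.copy()
        start.sigma = 0.2
        start.theta = {"CL": 26.0, "V1": 11.0}
        start.covariate_effects = [pm.CovariateEffect("CL", "BW", 0.4, 10.0)]
        res = foce.fit(start, lds, estimate_omega=False, estimate_sigma=False,
                       cov_step=False, fd="3-point", maxiter=1000,
                       ftol=1e-14, gtol=1e-10)
        assert res.success
        assert res.model.theta["CL"] == pytest.approx(20.0, rel=1e-4)
        assert res.model.theta["V1"] == pytest.approx(15.0, rel=1e-4)
        assert res.model.covariate_effects[0].exponent == pytest.approx(
            0.75, abs=1e-4)

    def test_aic_definition(self):
        gen = onecpt_model()
        lds, _ = onecpt_dataset(gen, n_subj=8, seed=3)
        res = foce.fit(gen.copy(), lds, cov_step=False, maxiter=40)
        assert res.n_free == 5  # CL, V1, two IIV terms, sigma
        assert res.aic == pytest.approx(res.ofv + 2 * res.n_free, rel=1e-12)

    def test_covariance_step_outputs(self):
        gen = onecpt_model()
        lds, _ = onecpt_dataset(gen, n_subj=24, seed=4)
        res = foce.fit(gen.copy(), lds, cov_step=True)
        assert res.success
        assert res.se_report is not None
        assert all(v >= 0 for v in res.se_report.values())
        assert res.condition_number >= 1.0
        tab = res.param_table()
        assert set(tab["parameter"]) == {"CL", "V1", "IIV CL", "IIV V1", "sigma"}
        assert tab["rse_percent"].notna().all()

    def test_fit_requires_free_parameters(self, ref_model):
        m = ref_model.copy()
        m.theta_fixed = set(m.param_names)
        m.iiv_fixed = set(m.iiv)
        m.sigma_fixed = True
        m.covariate_effects = [
            pm.CovariateEffect(e.parameter, e.covariate, e.exponent,
                               e.center, fixed=True)
            for e in m.covariate_effects]
        with pytest.raises(ValueError):
            foce.fit(m, None)


# ---------------------------------------------------------------------------
# EBEs and shrinkage
# ---------------------------------------------------------------------------

class TestEBEs:
    def test_prior_dominates_as_omega_vanishes(self):
        gen = onecpt_model()
        lds, _ = onecpt_dataset(gen, n_subj=6, seed=6)
        small = gen.copy()
        small.iiv = {"CL": 1e-10, "V1": 1e-10}
        ebes, _ = foce.compute_ebes(small, lds)
        assert np.abs(ebes[["eta_CL", "eta_V1"]].to_numpy()).max() < 1e-4

    def test_likelihood_dominates_as_sigma_vanishes(self):
        gen = onecpt_model(iiv_cl=0.25, iiv_v1=0.0, sigma=1e-12)
        gen.iiv_fixed = {"V1"}
        lds, etas = onecpt_dataset(gen, n_subj=10, seed=7)
        posthoc = gen.copy()
        posthoc.sigma = 1e-4
        ebes, ipars = foce.compute_ebes(posthoc, lds)
        merged = ebes.merge(etas, on="id", suffixes=("_hat", "_true"))
        np.testing.assert_allclose(merged["eta_CL_hat"],
                                   merged["eta_CL_true"], atol=1e-3)
        # realized individual parameters attached and consistent
        assert ipars[0].params["CL"] == pytest.approx(
            20.0 * np.exp(ebes["eta_CL"].iloc[0]), rel=1e-9)

    def test_identical_subjects_get_identical_modes(self):
        gen = onecpt_model()
        lds, _ = onecpt_dataset(gen, n_subj=1, seed=8)
        rec = lds.records.copy()
        twin = rec.copy()
        twin["id"] = "clone"
        both = dio.PKDataset(pd.concat([rec, twin], ignore_index=True),
                             loq=lds.loq, log_scale=True)
        ebes, _ = foce.compute_ebes(gen, both)
        assert ebes["eta_CL"].iloc[0] == pytest.approx(
            ebes["eta_CL"].iloc[1], abs=1e-10)


class TestShrinkage:
    def test_complete_shrinkage(self):
        ebes = pd.DataFrame({"eta_CL": [0.0, 0.0, 0.0]})
        out = foce.shrinkage(ebes, {"CL": 0.04})
        assert out["CL"] == pytest.approx(100.0)

    def test_no_shrinkage_when_sd_matches_omega(self):
        vals = np.array([0.3, -0.3])  # ddof=1 SD exactly 0.4243
        ebes = pd.DataFrame({"eta_CL": vals})
        out = foce.shrinkage(ebes, {"CL": float(np.var(vals, ddof=1))})
        assert out["CL"] == pytest.approx(0.0, abs=1e-10)

    def test_worked_example(self):
        ebes = pd.DataFrame({"eta_CL": [0.1, -0.1]})
        out = foce.shrinkage(ebes, {"CL": 0.2**2})
        assert out["CL"] == pytest.approx(100 * (1 - 0.14142 / 0.2), abs=0.05)

    def test_fixed_zero_elements_not_applicable(self, ref_model):
        ebes = pd.DataFrame({"eta_CL": [0.1, -0.1]})
        out = foce.shrinkage(ebes, ref_model)
        assert out["Q"] is None and out["Ka2"] is None and out["Tlag"] is None


# ---------------------------------------------------------------------------
# reporting conventions
# ---------------------------------------------------------------------------

class TestRSEConventions:
    def test_fixed_effect(self):
        assert foce.rse(395.0, 31.8) == pytest.approx(8.05, abs=0.005)

    def test_variance_reported_on_sd_scale(self):
        assert foce.rse(0.175, 0.0462, "variance") == pytest.approx(13.20, abs=0.005)

    def test_residual_sd(self):
        assert foce.rse(0.228, 0.0291, "sigma") == pytest.approx(12.76, abs=0.005)

    def test_zero_se_gives_zero_rse(self):
        assert foce.rse(1.0, 0.0) == 0.0
        assert foce.rse(0.0, 0.0) == 0.0

    def test_zero_estimate_flagged(self):
        with pytest.raises(ZeroDivisionError):
            foce.rse(0.0, 1.0)


class TestConditionNumber:
    def test_identity_correlation(self):
        assert foce.condition_number(np.eye(3)) == pytest.approx(1.0)

    def test_two_by_two_closed_form(self):
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        assert foce.condition_number(cov) == pytest.approx(9.0, rel=1e-10)

    def test_scale_invariance(self):
        cov = np.array([[4.0, 1.6], [1.6, 1.0]])  # corr 0.8 after scaling
        assert foce.condition_number(cov) == pytest.approx(9.0, rel=1e-10)

    def test_threshold_flag(self):
        assert not foce.condition_number_acceptable(1500.0)
        assert foce.condition_number_acceptable(999.0)

    def test_non_positive_definite_reports_inf(self):
        cov = np.array([[1.0, 2.0], [2.0, 1.0]])
        assert foce.condition_number(cov) == np.inf
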