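import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.signal import argrelmax

from desmopk import kinetics as K
from desmopk.synthetic_cohort import STUDY_TIMES, DOSE_PG


def _random_params(rng):
    """Lognormal scatter around the typical values (valid by construction)."""
    jitter = lambda v, s=0.4: float(v * np.exp(rng.normal(0, s)))
    return K.StructuralParams(
        CL=jitter(395), V1=jitter(131), Q=jitter(32), V2=jitter(436),
        Ka1=jitter(0.275), Ka2=jitter(0.399),
        Bio=float(1 / (1 + np.exp(-(np.log(0.86 / 0.14) + rng.normal(0, 0.8))))),
        Tlag=jitter(1.0, 0.2), D1=jitter(0.16, 0.3))


def _rel_err(a, b):
    scale = np.maximum(np.abs(b), 1e-9 * np.max(np.abs(b)))
    return np.max(np.abs(a - b) / scale)


class TestClosedForm:
    def test_zero_at_dose_time(self, typical_params):
        assert K.concentration_profile(typical_params, DOSE_PG, [0.0])[0] == 0.0

    def test_zero_dose_gives_zero_profile(self, typical_params):
        c = K.concentration_profile(typical_params, 0.0, STUDY_TIMES)
        np.testing.assert_array_equal(c, 0.0)

    def test_matches_ode_oracle_on_study_schedule(self, typical_params):
        c = K.concentration_profile(typical_params, DOSE_PG, STUDY_TIMES)
        co = K.concentration_profile_ode(typical_params, DOSE_PG, STUDY_TIMES)
        assert _rel_err(c, co) <= 1e-6

    def test_matches_ode_oracle_on_random_draws(self, typical_params):
        rng = np.random.default_rng(42)
        times = np.concatenate([STUDY_TIMES, [0.16, 1.0, 0.9999, 1.0001]])
        times.sort()
        worst = 0.0
        for _ in range(50):
            p = _random_params(rng)
            c = K.concentration_profile(p, DOSE_PG, times)
            co = K.concentration_profile_ode(p, DOSE_PG, times)
            worst = max(worst, _rel_err(c, co))
        assert worst <= 1e-6

    def test_double_peak_for_reference_parameters(self, typical_params):
        t = np.linspace(0.01, 8.0, 4000)
        c = K.concentration_profile(typical_params, DOSE_PG, t)
        peaks = argrelmax(c)[0]
        assert len(peaks) >= 2  # buccal peak then post-lag gastrointestinal peak

    def test_continuity_at_input_discontinuities(self, typical_params):
        for t0 in (typical_params.D1, typical_params.Tlag):
            left, right = K.concentration_profile(
                typical_params, DOSE_PG, [t0 - 1e-9, t0 + 1e-9])
            assert right == pytest.approx(left, rel=1e-6)

    def test_dose_linearity(self, typical_params):
        c1 = K.concentration_profile(typical_params, DOSE_PG, STUDY_TIMES)
        c3 = K.concentration_profile(typical_params, 3.0 * DOSE_PG, STUDY_TIMES)
        np.testing.assert_allclose(c3, 3.0 * c1, rtol=1e-12)

    def test_batched_parameters_match_scalar_loop(self, typical_params):
        rng = np.random.default_rng(3)
        draws = [_random_params(rng) for _ in range(6)]
        batch = {k: np.array([getattr(p, k) for p in draws])
                 for k in K.PARAM_NAMES}
        out = K.concentration_profile(batch, DOSE_PG, STUDY_TIMES)
        for i, p in enumerate(draws):
            np.testing.assert_allclose(
                out[i], K.concentration_profile(p, DOSE_PG, STUDY_TIMES),
                rtol=1e-12)

    def test_absorption_rate_equal_to_eigenvalue_is_finite(self, typical_params):
        lam1, lam2, _ = K.disposition_eigenvalues(395.0, 131.0, 32.0, 436.0)
        for ka in (lam1, lam2, lam1 * (1 + 1e-10)):
            p = K.StructuralParams(CL=395, V1=131, Q=32, V2=436, Ka1=float(ka),
                                   Ka2=float(ka), Bio=0.86, Tlag=1.0, D1=0.16)
            c = K.concentration_profile(p, DOSE_PG, STUDY_TIMES)
            assert np.all(np.isfinite(c))
            co = K.concentration_profile_ode(p, DOSE_PG, STUDY_TIMES)
            assert _rel_err(c, co) <= 1e-6

    def test_bio_to_one_reduces_to_single_input_model(self, typical_params):
        """Bio -> 1: the profile equals a zero-order + first-order single-input
        two-compartment model, checked against direct numerical convolution of
        the depot outflow with the disposition impulse response."""
        p = K.StructuralParams(CL=395, V1=131, Q=32, V2=436, Ka1=0.275,
                               Ka2=0.399, Bio=1 - 1e-12, Tlag=1.0, D1=0.16)
        lam1, lam2, k21 = K.disposition_eigenvalues(p.CL, p.V1, p.Q, p.V2)
        c1 = (lam1 - k21) / (lam1 - lam2)
        c2 = (k21 - lam2) / (lam1 - lam2)
        rate = DOSE_PG / p.D1

        def depot1(s):  # textbook zero-order-filled depot amount
            if s <= p.D1:
                return rate / p.Ka1 * (1 - np.exp(-p.Ka1 * s))
            a_d1 = rate / p.Ka1 * (1 - np.exp(-p.Ka1 * p.D1))
            return a_d1 * np.exp(-p.Ka1 * (s - p.D1))

        def impulse(u):
            return c1 * np.exp(-lam1 * u) + c2 * np.exp(-lam2 * u)

        for t in (0.1, 0.16, 0.5, 2.0, 6.0):
            central, _ = quad(lambda s: p.Ka1 * depot1(s) * impulse(t - s),
                              0.0, t, limit=200, points=[p.D1] if t > p.D1 else None)
            expect = central / (p.V1 * 1000.0)
            got = K.concentration_profile(p, DOSE_PG, [t])[0]
            assert got == pytest.approx(expect, rel=1e-7)


class TestMassBalanceAndAUC:
    def test_mass_balance_at_24h(self, typical_params):
        st_ = K.amounts_ode(typical_params, DOSE_PG, [24.0])
        assert st_.total()[0] == pytest.approx(DOSE_PG, rel=1e-8)

    def test_all_states_nonnegative(self, typical_params):
        st_ = K.amounts_ode(typical_params, DOSE_PG, np.linspace(0.05, 24, 40))
        for arr in (st_.depot1, st_.depot2, st_.central, st_.peripheral,
                    st_.eliminated):
            assert np.all(arr >= -1e-6 * DOSE_PG)

    def test_auc_equals_dose_over_clearance(self, typical_params):
        # fine-grid quadrature of the noise-free typical curve
        t = np.concatenate([[0], np.geomspace(1e-4, 400.0, 120000)])
        c = K.concentration_profile(typical_params, DOSE_PG, t)
        auc = np.trapezoid(c, t)
        assert auc == pytest.approx(DOSE_PG / (typical_params.CL * 1000.0),
                                    rel=1e-4)

    def test_auc_independent_of_absorption_parameters(self):
        rng = np.random.default_rng(11)
        t = np.concatenate([[0], np.geomspace(1e-4, 600.0, 60000)])
        for _ in range(3):
            p = K.StructuralParams(
                CL=395, V1=131, Q=32, V2=436,
                Ka1=float(rng.uniform(0.1, 2)), Ka2=float(rng.uniform(0.1, 2)),
                Bio=float(rng.uniform(0.2, 0.95)),
                Tlag=float(rng.uniform(0.2, 3)), D1=float(rng.uniform(0.05, 1)))
            auc = np.trapezoid(K.concentration_profile(p, DOSE_PG, t), t)
            assert auc == pytest.approx(DOSE_PG / (p.CL * 1000.0), rel=1e-3)


class TestValidation:
    @pytest.mark.parametrize("field,value", [
        ("CL", 0.0), ("V1", -1.0), ("Bio", 1.0), ("Bio", 0.0), ("D1", 0.0),
    ])
    def test_invalid_parameters_rejected(self, field, value):
        good = dict(CL=395, V1=131, Q=32, V2=436, Ka1=0.275, Ka2=0.399,
                    Bio=0.86, Tlag=1.0, D1=0.16)
        good[field] = value
        with pytest.raises(ValueError):
            K.StructuralParams(**good)

    def test_ode_rejects_bad_tolerance(self, typical_params):
        with pytest.raises(ValueError):
            K.concentration_profile_ode(typical_params, DOSE_PG, [1.0], rtol=1.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(scale=st.floats(0.1, 10.0), seed=st.integers(0, 10_000))
def test_profile_scales_linearly_in_dose(scale, seed):
    p = _random_params(np.random.default_rng(seed))
    base = K.concentration_profile(p, DOSE_PG, STUDY_TIMES)
    scaled = K.concentration_profile(p, scale * DOSE_PG, STUDY_TIMES)
    np.testing.assert_allclose(scaled, scale * base, rtol=1e-10)
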