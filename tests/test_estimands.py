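"""PCE/CACE contrasts, Wald tests, LRT, model comparison."""

import numpy as np
import pytest
import scipy.stats

import mcace
from mcace import FitResult, cace, compare_models, global_lrt, pce, wald_test
from mcace.estimands import _contrast
from mcace.parameters import ParamLayout


def _fit_with(spec, beta_c, vcov_beta_c=None, loglik=-100.0):
    """A FitResult carrying given complier treatment coefficients."""
    layout = ParamLayout(spec)
    pv = mcace.ParamVector(
        lambda0={m: np.zeros(spec.K) for m in ("c", "n")},
        loadings=np.ones(spec.loading.n_free),
        xi={m: np.ones(spec.K) for m in ("c", "n")},
        tau2={m: np.ones(spec.K) for m in ("c", "n")},
        beta={"c": np.asarray(beta_c, float), "n": np.zeros(layout.beta_len["n"])},
        sigma_v=[0.3 * np.eye(r) for r in layout.rand_dims],
        eta=np.zeros(spec.n_eta),
    )
    vcov = np.eye(layout.n_free) * 1e-4
    if vcov_beta_c is not None:
        s = layout.slices["beta_c"]
        vcov[s, s] = vcov_beta_c
    return FitResult(
        params_hat=pv,
        loglik=loglik,
        converged=True,
        n_free=layout.n_free,
        n_subjects=94,
        layout=layout,
        spec=spec,
        grad_norm=0.0,
        vcov=vcov,
    )


@pytest.fixture(scope="module")
def quad_spec(ahj_cfg):
    """Quadratic two-factor spec: complier terms t, t2, D:t, D:t2."""
    return ahj_cfg.spec


class TestContrasts:
    def test_final_visit_contrast_is_2_4(self, quad_spec):
        layout = ParamLayout(quad_spec)
        c, idx = _contrast(layout, quad_spec, 0, "c", 2, np.array([0.0, 1.0, 2.0]))
        np.testing.assert_array_equal(c, [0, 0, 2, 4])

    @pytest.mark.parametrize("t", [0.0, 1.0, 2.0])
    def test_cace_is_treatment_polynomial_in_time(self, quad_spec, t):
        """CACE(t) = beta_Dt * t + beta_Dt2 * t^2 under the quadratic spec."""
        layout = ParamLayout(quad_spec)
        j = [0.0, 1.0, 2.0].index(t)
        c, idx = _contrast(layout, quad_spec, 1, "c", j, np.array([0.0, 1.0, 2.0]))
        terms = layout.beta_terms["c"][1]
        manual = np.zeros(len(terms))
        manual[terms.index("D:t")] = t
        manual[terms.index("D:t2")] = t * t
        np.testing.assert_allclose(c, manual)


class TestPceCace:
    def test_never_taker_pce_is_zero(self, quad_spec):
        fit = _fit_with(quad_spec, beta_c=[0.4, -0.1, 2.0, -0.5] * 2)
        for q in range(quad_spec.Q):
            for j in range(3):
                rep = pce(fit, quad_spec, q, "n", j)
                assert rep.estimate == 0.0 and rep.p == 1.0

    def test_baseline_visit_effect_is_zero(self, quad_spec):
        fit = _fit_with(quad_spec, beta_c=[0.4, -0.1, 2.0, -0.5] * 2)
        rep = cace(fit, quad_spec, 0, 0)
        assert rep.estimate == 0.0

    def test_final_visit_worked_arithmetic(self, quad_spec):
        """beta_Dt = 2.772, beta_Dt2 = -1.038 combine to 2*2.772 - 4*1.038."""
        fit = _fit_with(quad_spec, beta_c=[0.0, 0.0, 2.772, -1.038, 0, 0, 1.9, -0.514])
        rep = cace(fit, quad_spec, 0, 2)
        assert rep.estimate == pytest.approx(1.392, abs=1e-12)
        rep2 = cace(fit, quad_spec, 1, 2)
        assert rep2.estimate == pytest.approx(1.744, abs=1e-12)

    def test_cace_linearity_in_beta(self, quad_spec):
        beta = np.array([0.4, -0.1, 2.0, -0.5] * 2)
        r1 = cace(_fit_with(quad_spec, beta), quad_spec, 0, 2)
        r2 = cace(_fit_with(quad_spec, 2 * beta), quad_spec, 0, 2)
        assert r2.estimate == pytest.approx(2 * r1.estimate)

    def test_delta_method_closed_form(self, quad_spec):
        """For the (2, 4) contrast, se^2 = 4 V11 + 16 V22 + 16 V12."""
        rng = np.random.default_rng(0)
        A = rng.normal(size=(4, 4))
        V = A @ A.T
        fit = _fit_with(
            quad_spec,
            beta_c=[0.4, -0.1, 2.0, -0.5, 0.4, -0.1, 2.0, -0.5],
            vcov_beta_c=np.kron(np.eye(2), V),
        )
        rep = cace(fit, quad_spec, 0, 2)
        expected = np.sqrt(4 * V[2, 2] + 16 * V[3, 3] + 16 * V[2, 3])
        assert rep.se == pytest.approx(expected, rel=1e-10)

    def test_visit_outside_schedule_rejected(self, quad_spec):
        fit = _fit_with(quad_spec, beta_c=np.zeros(8))
        with pytest.raises(ValueError, match="schedule"):
            cace(fit, quad_spec, 0, 7)


class TestWald:
    @pytest.mark.parametrize(
        "est,se,expected",
        [(2.772, 1.204, 0.021), (1.745, 0.660, 0.008), (1.392, 0.632, 0.028)],
    )
    def test_reported_pairs_reproduce_printed_pvalues(self, est, se, expected):
        _, p = wald_test(est, se)
        assert round(p, 3) == expected

    def test_null_estimate_gives_p_one(self):
        z, p = wald_test(0.0, 2.0)
        assert z == 0.0 and p == 1.0

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_test(1.0, 0.0)


class TestGlobalLrt:
    def _dummy(self, loglik, n_free=10, spec=None):
        return FitResult(
            params_hat=None,
            loglik=loglik,
            converged=True,
            n_free=n_free,
            n_subjects=100,
            layout=None,
            spec=spec,
            grad_norm=0.0,
        )

    def test_identical_fits_give_null_result(self):
        t = global_lrt(self._dummy(-50.0), self._dummy(-50.0), 2)
        assert t.statistic == 0.0 and t.p == 1.0

    def test_chi2_quantile_identity(self):
        t = global_lrt(self._dummy(-50.0), self._dummy(-50.0 - 5.991 / 2), 2)
        assert t.p == pytest.approx(0.05, abs=2e-4)
        assert t.statistic == pytest.approx(5.991)

    def test_negative_deviance_raises(self):
        with pytest.raises(RuntimeError, match="refit"):
            global_lrt(self._dummy(-51.0), self._dummy(-50.0), 2)

    def test_tiny_negative_clipped(self):
        t = global_lrt(self._dummy(-50.0 - 1e-8), self._dummy(-50.0), 2)
        assert t.statistic == 0.0


class TestCompareModels:
    def _dummy(self, loglik, n_free):
        return FitResult(
            params_hat=None,
            loglik=loglik,
            converged=True,
            n_free=n_free,
            n_subjects=100,
            layout=None,
            spec=None,
            grad_norm=0.0,
        )

    def test_single_fit_returns_itself(self):
        table = compare_models([self._dummy(-100.0, 5)], labels=["only"])
        assert list(table["model"]) == ["only"]

    def test_equal_loglik_prefers_fewer_parameters(self):
        table = compare_models(
            [self._dummy(-100.0, 12), self._dummy(-100.0, 7)], labels=["big", "small"]
        )
        assert list(table["model"]) == ["small", "big"]
        assert table.loc[0, "AIC"] == pytest.approx(214.0)

    def test_mixed_datasets_rejected(self):
        a = self._dummy(-100.0, 5)
        b = self._dummy(-90.0, 5)
        b.n_subjects = 50
        with pytest.raises(ValueError, match="different datasets"):
            compare_models([a, b])
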