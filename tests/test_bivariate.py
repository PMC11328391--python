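"""Bivariate binomial-normal model: quadrature, fitting, DOR, ellipses, SROC."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

from armspill.arm_data import TwoByTwo
from armspill.bivariate import (
    BivariateFit,
    confidence_ellipse,
    fit_bivariate,
    loglik_brute_force,
    loglik_quadrature,
    prediction_ellipse,
    sroc_curve,
    summary_dor,
)


class TestQuadrature:
    @pytest.mark.parametrize(
        "params",
        [
            (-1.0, -0.5, 0.6, 0.7, 0.3),
            (-2.0, -1.5, 0.3, 0.3, -0.6),
            (0.5, 0.0, 1.2, 0.8, 0.0),
        ],
    )
    def test_matches_brute_force(self, toy_pairs, params):
        """Adaptive quadrature at oracle-grade order agrees with dense 2-D
        grid integration."""
        q = loglik_quadrature(toy_pairs, *params, quad_order=15)
        b = loglik_brute_force(toy_pairs, *params, step=0.02)
        assert q == pytest.approx(b, abs=1e-5)

    def test_higher_order_converges(self, toy_pairs):
        params = (-1.0, -0.5, 0.6, 0.7, 0.3)
        q7 = loglik_quadrature(toy_pairs, *params, quad_order=7)
        q15 = loglik_quadrature(toy_pairs, *params, quad_order=15)
        assert q7 == pytest.approx(q15, abs=1e-5)


class TestFit:
    def test_mirror_symmetric_data(self):
        """Appending every study with its arms swapped forces a symmetric fit."""
        base = [TwoByTwo(5, 45, 15, 35), TwoByTwo(8, 72, 20, 60), TwoByTwo(3, 37, 9, 31),
                TwoByTwo(11, 59, 22, 48)]
        mirrored = base + [TwoByTwo(t.fp, t.tn, t.tp, t.fn) for t in base]
        fit = fit_bivariate(mirrored)
        assert fit.mu_I == pytest.approx(fit.mu_C, abs=1e-4)
        assert fit.sigma_I == pytest.approx(fit.sigma_C, abs=1e-4)

    def test_degenerate_common_incidence_recovery(self):
        """sigma = 0 truth: all studies share incidences 0.2 / 0.4."""
        rng = np.random.default_rng(11)
        k, n = 50, 500
        pairs = [
            TwoByTwo(
                int(rng.binomial(n, 0.2)), 0, int(rng.binomial(n, 0.4)), 0
            )
            for _ in range(k)
        ]
        pairs = [TwoByTwo(t.tp, n - t.tp, t.fp, n - t.fp) for t in pairs]
        fit = fit_bivariate(pairs)
        se = math.sqrt(max(fit.vcov_fixed[0][0], 1e-12))
        assert abs(fit.mu_I - logit(0.2)) < max(3 * se, 0.05)
        se_c = math.sqrt(max(fit.vcov_fixed[1][1], 1e-12))
        assert abs(fit.mu_C - logit(0.4)) < max(3 * se_c, 0.05)
        assert fit.sigma_I < 0.1
        assert fit.sigma_C < 0.1

    def test_few_studies_warns(self, toy_pairs):
        with pytest.warns(UserWarning, match="weakly identified"):
            fit_bivariate(toy_pairs)


def _fit_like(mu_I, mu_C, sI=0.5, sC=0.5, rho=0.2, vcov=None, k=20):
    return BivariateFit(
        mu_I=mu_I,
        mu_C=mu_C,
        sigma_I=sI,
        sigma_C=sC,
        rho=rho,
        vcov_fixed=np.asarray(vcov if vcov is not None else 0.01 * np.eye(2)),
        loglik=0.0,
        converged=True,
        k=k,
    )


class TestDor:
    def test_known_incidences(self):
        fit = _fit_like(logit(0.2), logit(0.5))
        dor, _ = summary_dor(fit)
        assert dor == pytest.approx(0.25, rel=1e-9)

    def test_equal_means_ci_contains_one(self):
        fit = _fit_like(-1.0, -1.0)
        dor, (lo, hi) = summary_dor(fit)
        assert dor == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_arm_swap_refit_inverts_dor(self):
        """Refitting with every study's arms exchanged inverts the summary OR
        (well-identified heterogeneous data, interior optimum)."""
        from scipy.special import expit

        rng = np.random.default_rng(5)
        pairs = []
        for _ in range(30):
            n1, n2 = int(rng.integers(60, 160)), int(rng.integers(60, 160))
            eta_c = rng.normal(-0.8, 0.5)
            eta_i = eta_c + rng.normal(-0.5, 0.3)
            tp = int(rng.binomial(n1, expit(eta_i)))
            fp = int(rng.binomial(n2, expit(eta_c)))
            pairs.append(TwoByTwo(tp, n1 - tp, fp, n2 - fp))
        swapped = [TwoByTwo(t.fp, t.tn, t.tp, t.fn) for t in pairs]
        d1, _ = summary_dor(fit_bivariate(pairs))
        d2, _ = summary_dor(fit_bivariate(swapped))
        assert d1 == pytest.approx(1.0 / d2, abs=1e-6)


class TestEllipses:
    def test_identity_cov_radius_is_chi2_quantile(self):
        """With unit fixed-effect covariance the logit-plane radius is
        sqrt(chi2_2 quantile) = 2.4477 in every direction."""
        fit = _fit_like(0.0, 0.0, vcov=np.eye(2))
        ell = confidence_ellipse(fit, level=0.95)
        eta = logit(ell.points)
        radii = np.hypot(eta[:, 0], eta[:, 1])
        assert np.allclose(radii, math.sqrt(stats.chi2.ppf(0.95, 2)), atol=1e-8)

    def test_prediction_contains_confidence(self):
        fit = _fit_like(-1.0, -0.5, sI=0.6, sC=0.8, rho=0.3,
                        vcov=np.array([[0.02, 0.005], [0.005, 0.03]]))
        conf = logit(confidence_ellipse(fit).points)
        pred = logit(prediction_ellipse(fit).points)

        def area(p):
            x, y = p[:, 0], p[:, 1]
            return 0.5 * abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))

        assert area(pred) > area(conf)

    def test_paths_closed_and_inside_unit_square(self):
        fit = _fit_like(-1.0, -0.5)
        for ell in (confidence_ellipse(fit), prediction_ellipse(fit)):
            assert np.all((ell.points > 0) & (ell.points < 1))
            assert np.allclose(ell.points[0], ell.points[-1])

    def test_center_is_summary_point(self):
        fit = _fit_like(-1.2, -0.4)
        pts = confidence_ellipse(fit, n_points=201).points
        cx, cy = fit.summary_point
        # symmetric parameter sweep: opposite points average to the centre
        mid = (logit(pts[0]) + logit(pts[100])) / 2
        assert expit(mid[0]) == pytest.approx(cx, abs=1e-6)
        assert expit(mid[1]) == pytest.approx(cy, abs=1e-6)

    def test_f_scaling_larger_for_small_k(self):
        fit = _fit_like(-1.0, -0.5, k=10, vcov=np.eye(2))
        chi = confidence_ellipse(fit, scaling="chi2").points
        fsc = confidence_ellipse(fit, scaling="f").points
        assert np.max(np.abs(logit(fsc))) > np.max(np.abs(logit(chi)))


class TestSrocCurve:
    def test_zero_rho_is_horizontal(self):
        fit = _fit_like(-1.0, -0.5, rho=0.0)
        curve = sroc_curve(fit)
        assert np.allclose(curve.points[:, 1], expit(-1.0))

    def test_passes_through_summary_point(self):
        fit = _fit_like(-1.0, -0.5, rho=0.4)
        x0 = expit(-0.5)
        curve = sroc_curve(fit, x_grid=np.array([x0]))
        assert curve.points[0, 1] == pytest.approx(expit(-1.0), abs=1e-12)

    def test_monotone_when_rho_positive(self):
        fit = _fit_like(-1.0, -0.5, rho=0.7)
        curve = sroc_curve(fit)
        assert np.all(np.diff(curve.points[:, 0]) > 0)
        assert np.all(np.diff(curve.points[:, 1]) > 0)

    def test_sigma_c_zero_vertical_reference(self):
        fit = _fit_like(-1.0, -0.5, sC=0.0)
        with pytest.warns(UserWarning, match="sigma_C"):
            curve = sroc_curve(fit)
        assert np.allclose(curve.points[:, 0], expit(-0.5))
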