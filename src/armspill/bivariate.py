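"""Bivariate binomial-normal random-effects model over paired trial arms.

This is the diagnostic-test-assessment core: each study contributes binomial
event counts in its intervention and control arms, whose true logit incidences
(eta_I, eta_C) are drawn from a bivariate normal with means (mu_I, mu_C),
standard deviations (sigma_I, sigma_C) and correlation rho. In the DTA
mapping, expit(mu_I) is the summary "sensitivity" (intervention incidence) and
expit(mu_C) the summary "1 - specificity" (control incidence); mu_I - mu_C is
the log diagnostic odds ratio.

The marginal likelihood integrates the two random effects out per study:

    L_i = integral of Bin(eI_i; nI_i, expit(eta_I)) Bin(eC_i; nC_i, expit(eta_C))
          N2(eta; mu, Sigma) over the (eta_I, eta_C) plane

evaluated by adaptive Gauss-Hermite quadrature: the integrand's mode and
curvature are found per study by Newton iteration and the tensor-product
Hermite rule is recentred and rescaled there. A dense-grid brute-force
integrator is provided as an independent slow reference path.

Parameters are optimised on an unconstrained scale (log sigmas, Fisher-z rho)
and the fixed-effect covariance is the (mu_I, mu_C) block of the inverse
observed information.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, gammaln

from .arm_data import TwoByTwo

logger = logging.getLogger(__name__)

__all__ = [
    "BivariateFit",
    "EllipsePath",
    "SrocCurve",
    "fit_bivariate",
    "loglik_quadrature",
    "loglik_brute_force",
    "summary_dor",
    "confidence_ellipse",
    "prediction_ellipse",
    "sroc_curve",
]

_LOG_SIGMA_BOUNDS = (-6.0, 3.0)
_ZRHO_BOUND = 6.0


@dataclass
class BivariateFit:
    mu_I: float
    mu_C: float
    sigma_I: float
    sigma_C: float
    rho: float
    vcov_fixed: np.ndarray  # 2x2 covariance of (mu_I, mu_C)
    loglik: float
    converged: bool
    k: int
    n_iter: int = 0
    message: str = ""
    quad_order: int = 7

    @property
    def Sigma(self) -> np.ndarray:
        """Random-effect covariance of (eta_I, eta_C)."""
        c = self.rho * self.sigma_I * self.sigma_C
        return np.array([[self.sigma_I**2, c], [c, self.sigma_C**2]])

    @property
    def summary_point(self) -> tuple[float, float]:
        """(control incidence, intervention incidence) at the means."""
        return float(expit(self.mu_C)), float(expit(self.mu_I))

    def to_dict(self) -> dict:
        return {
            "mu_I": self.mu_I,
            "mu_C": self.mu_C,
            "sigma_I": self.sigma_I,
            "sigma_C": self.sigma_C,
            "rho": self.rho,
            "vcov_fixed": np.asarray(self.vcov_fixed).tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "k": self.k,
            "quad_order": self.quad_order,
        }


@dataclass(frozen=True)
class EllipsePath:
    kind: str  # "confidence" | "prediction"
    level: float
    points: np.ndarray  # (m, 2) closed polyline, columns (control, intervention)


@dataclass(frozen=True)
class SrocCurve:
    points: np.ndarray  # (m, 2), columns (control, intervention), x increasing
    parameterization_note: str


# ---------------------------------------------------------------------------
# likelihood machinery


def _unpack_pairs(pairs: list[TwoByTwo]) -> tuple[np.ndarray, ...]:
    eI = np.array([t.intervention_events for t in pairs], dtype=float)
    nI = np.array([t.intervention_total for t in pairs], dtype=float)
    eC = np.array([t.control_events for t in pairs], dtype=float)
    nC = np.array([t.control_total for t in pairs], dtype=float)
    return eI, nI, eC, nC


def _binom_const(e: np.ndarray, n: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(e + 1) - gammaln(n - e + 1)


def _sigma_inv(sI: float, sC: float, rho: float) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of the 2x2 random-effect covariance."""
    det = (sI * sC) ** 2 * (1.0 - rho**2)
    inv = (
        np.array(
            [[sC**2, -rho * sI * sC], [-rho * sI * sC, sI**2]]
        )
        / det
    )
    return inv, math.log(det)


def _study_loglik_agq(
    theta: np.ndarray,
    eI: np.ndarray,
    nI: np.ndarray,
    eC: np.ndarray,
    nC: np.ndarray,
    nodes: np.ndarray,
    logw2: np.ndarray,
    const: np.ndarray,
) -> np.ndarray:
    """Per-study marginal log-likelihood by adaptive Gauss-Hermite quadrature.

    theta = (mu_I, mu_C, sigma_I, sigma_C, rho) on the natural scale.
    """
    muI, muC, sI, sC, rho = theta
    k = len(eI)
    Sinv, logdet = _sigma_inv(sI, sC, rho)
    a11, a12, a22 = Sinv[0, 0], Sinv[0, 1], Sinv[1, 1]

    # Newton iteration for the joint-density mode per study, vectorised.
    x = np.column_stack(
        [
            np.log((eI + 0.5) / (nI - eI + 0.5)),
            np.log((eC + 0.5) / (nC - eC + 0.5)),
        ]
    )  # start at empirical logits
    mu = np.array([muI, muC])
    for _ in range(50):
        pI = expit(x[:, 0])
        pC = expit(x[:, 1])
        d = x - mu
        g1 = eI - nI * pI - (a11 * d[:, 0] + a12 * d[:, 1])
        g2 = eC - nC * pC - (a12 * d[:, 0] + a22 * d[:, 1])
        h11 = nI * pI * (1 - pI) + a11
        h22 = nC * pC * (1 - pC) + a22
        h12 = np.full(k, a12)
        det = h11 * h22 - h12**2
        s1 = (h22 * g1 - h12 * g2) / det
        s2 = (h11 * g2 - h12 * g1) / det
        x[:, 0] += s1
        x[:, 1] += s2
        if max(np.max(np.abs(s1)), np.max(np.abs(s2))) < 1e-10:
            break

    # curvature at the mode -> per-study scaling L with L L' = H^{-1}
    pI = expit(x[:, 0])
    pC = expit(x[:, 1])
    h11 = nI * pI * (1 - pI) + a11
    h22 = nC * pC * (1 - pC) + a22
    h12 = np.full(k, a12)
    # Cholesky of H^{-1} analytically: H^{-1} = [[h22,-h12],[-h12,h11]]/det
    det = h11 * h22 - h12**2
    q11 = h22 / det
    q12 = -h12 / det
    q22 = h11 / det
    l11 = np.sqrt(q11)
    l21 = q12 / l11
    l22 = np.sqrt(np.maximum(q22 - l21**2, 1e-300))
    logdetL = np.log(l11) + np.log(l22)

    # tensor nodes: eta = mode + sqrt(2) * L z, z = (z1, z2)
    z1 = nodes[:, 0]
    z2 = nodes[:, 1]
    etaI = x[:, 0][:, None] + math.sqrt(2.0) * (l11[:, None] * z1[None, :])
    etaC = x[:, 1][:, None] + math.sqrt(2.0) * (
        l21[:, None] * z1[None, :] + l22[:, None] * z2[None, :]
    )

    dI = etaI - muI
    dC = etaC - muC
    quad = a11 * dI**2 + 2 * a12 * dI * dC + a22 * dC**2
    g = (
        eI[:, None] * etaI
        - nI[:, None] * np.logaddexp(0.0, etaI)
        + eC[:, None] * etaC
        - nC[:, None] * np.logaddexp(0.0, etaC)
        - 0.5 * quad
        - math.log(2 * math.pi)
        - 0.5 * logdet
    )
    # \int e^{g} d eta ~= 2 |L| sum_j w_j e^{z_j^2} e^{g_j}
    contrib = logw2[None, :] + (z1**2 + z2**2)[None, :] + g
    m = np.max(contrib, axis=1)
    ll = m + np.log(np.sum(np.exp(contrib - m[:, None]), axis=1))
    return ll + math.log(2.0) + logdetL + const


def _gh_nodes(order: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(order)
    z = np.array([(a, b) for a in x for b in x])
    logw = np.log(w)
    logw2 = np.array([la + lb for la in logw for lb in logw])
    return z, logw2


def loglik_quadrature(
    pairs: list[TwoByTwo],
    mu_I: float,
    mu_C: float,
    sigma_I: float,
    sigma_C: float,
    rho: float,
    quad_order: int = 7,
) -> float:
    """Total marginal log-likelihood at fixed parameters (adaptive GH)."""
    eI, nI, eC, nC = _unpack_pairs(pairs)
    const = _binom_const(eI, nI) + _binom_const(eC, nC)
    nodes, logw2 = _gh_nodes(quad_order)
    theta = np.array([mu_I, mu_C, sigma_I, sigma_C, rho])
    return float(
        np.sum(_study_loglik_agq(theta, eI, nI, eC, nC, nodes, logw2, const))
    )


def loglik_brute_force(
    pairs: list[TwoByTwo],
    mu_I: float,
    mu_C: float,
    sigma_I: float,
    sigma_C: float,
    rho: float,
    span: float = 10.0,
    step: float = 0.01,
) -> float:
    """Slow dense-grid reference for the marginal log-likelihood.

    Trapezoidal integration of the joint density over [-span, span]^2 on the
    logit plane; independent of the quadrature path and used to validate it.
    """
    grid = np.arange(-span, span + step / 2, step)
    Sinv, logdet = _sigma_inv(sigma_I, sigma_C, rho)
    a11, a12, a22 = Sinv[0, 0], Sinv[0, 1], Sinv[1, 1]
    dI = grid - mu_I  # eta_I axis
    dC = grid - mu_C  # eta_C axis
    lbinom_base = -math.log(2 * math.pi) - 0.5 * logdet
    total = 0.0
    for tt in pairs:
        lI = (
            tt.intervention_events * grid
            - tt.intervention_total * np.logaddexp(0.0, grid)
            + _binom_const(
                np.array(float(tt.intervention_events)),
                np.array(float(tt.intervention_total)),
            )
        )
        lC = (
            tt.control_events * grid
            - tt.control_total * np.logaddexp(0.0, grid)
            + _binom_const(
                np.array(float(tt.control_events)), np.array(float(tt.control_total))
            )
        )
        logf = (
            lI[:, None]
            + lC[None, :]
            - 0.5
            * (
                a11 * dI[:, None] ** 2
                + 2 * a12 * dI[:, None] * dC[None, :]
                + a22 * dC[None, :] ** 2
            )
            + lbinom_base
        )
        m = logf.max()
        integral = np.trapezoid(np.trapezoid(np.exp(logf - m), grid, axis=1), grid)
        total += m + math.log(integral)
    return float(total)


# ---------------------------------------------------------------------------
# fitting


def _to_natural(x: np.ndarray) -> np.ndarray:
    muI, muC, lsI, lsC, zr = x
    return np.array([muI, muC, math.exp(lsI), math.exp(lsC), math.tanh(zr)])


def fit_bivariate(
    pairs: list[TwoByTwo],
    quad_order: int = 7,
    starts: np.ndarray | None = None,
) -> BivariateFit:
    """Maximum-likelihood fit of the bivariate binomial-normal model.

    ``starts``, when given, is (mu_I, mu_C, sigma_I, sigma_C, rho) on the
    natural scale. With fewer than 4 studies the variance components are
    weakly identified; a warning is issued and the fit still attempted.
    """
    if quad_order < 3:
        raise ValueError("quad_order must be >= 3")
    k = len(pairs)
    if k < 2:
        raise ValueError("fit_bivariate requires at least 2 studies")
    if k < 4:
        warnings.warn(
            f"only {k} studies: bivariate variance components weakly identified",
            stacklevel=2,
        )

    eI, nI, eC, nC = _unpack_pairs(pairs)
    const = _binom_const(eI, nI) + _binom_const(eC, nC)
    nodes, logw2 = _gh_nodes(quad_order)

    def negll(x: np.ndarray) -> float:
        theta = _to_natural(x)
        try:
            ll = np.sum(
                _study_loglik_agq(theta, eI, nI, eC, nC, nodes, logw2, const)
            )
        except FloatingPointError:
            return 1e10
        if not np.isfinite(ll):
            return 1e10
        return -float(ll)

    if starts is None:
        yI = np.log((eI + 0.5) / (nI - eI + 0.5))
        yC = np.log((eC + 0.5) / (nC - eC + 0.5))
        starts = np.array([np.mean(yI), np.mean(yC), 0.5, 0.5, 0.0])
    s = np.asarray(starts, dtype=float)
    x0 = np.array(
        [
            s[0],
            s[1],
            math.log(max(s[2], 1e-3)),
            math.log(max(s[3], 1e-3)),
            math.atanh(min(max(s[4], -0.99), 0.99)),
        ]
    )
    bounds = [
        (None, None),
        (None, None),
        _LOG_SIGMA_BOUNDS,
        _LOG_SIGMA_BOUNDS,
        (-_ZRHO_BOUND, _ZRHO_BOUND),
    ]
    with np.errstate(over="ignore", under="ignore"):
        res = optimize.minimize(
            negll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
        )
        # derivative-free polish: L-BFGS-B with numeric gradients stalls a
        # few 1e-4 from the optimum, which matters for symmetry properties;
        # a tight initial simplex keeps this a local refinement
        simplex = np.tile(res.x, (6, 1))
        for i in range(5):
            simplex[i + 1, i] += 1e-3
        polish = optimize.minimize(
            negll, res.x, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-13, "maxiter": 1500,
                     "initial_simplex": simplex},
        )
        if polish.fun <= res.fun:
            res.x = polish.x
            res.fun = polish.fun
            res.nit += polish.nit
    theta = _to_natural(res.x)
    muI, muC, sI, sC, rho = theta
    if abs(res.x[4]) > 0.95 * _ZRHO_BOUND:
        warnings.warn("rho at the boundary of its Fisher-z range", stacklevel=2)

    vcov = _fixed_vcov(negll, res.x)
    fit = BivariateFit(
        mu_I=float(muI),
        mu_C=float(muC),
        sigma_I=float(sI),
        sigma_C=float(sC),
        rho=float(rho),
        vcov_fixed=vcov,
        loglik=-float(res.fun),
        converged=bool(res.success),
        k=k,
        n_iter=int(res.nit),
        message=str(res.message),
        quad_order=quad_order,
    )
    if not res.success:
        logger.warning("bivariate fit did not converge: %s", res.message)
    return fit


def _fixed_vcov(negll, xhat: np.ndarray) -> np.ndarray:
    """(mu_I, mu_C) block of the inverse observed information.

    Central finite differences of the negative log-likelihood on the working
    scale; the mean parameters coincide with the natural scale so no Jacobian
    correction is needed for the returned block.
    """
    p = len(xhat)
    h = np.maximum(1e-4, 1e-4 * np.abs(xhat))
    H = np.zeros((p, p))
    f0 = negll(xhat)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (negll(xhat + ei) - 2 * f0 + negll(xhat - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    negll(xhat + ei + ej)
                    - negll(xhat + ei - ej)
                    - negll(xhat - ei + ej)
                    + negll(xhat - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    block = cov[:2, :2]
    # guard against a non-PSD numerical Hessian
    eigs = np.linalg.eigvalsh(block)
    if eigs.min() <= 0:
        logger.warning("observed information not positive definite; projecting")
        w, V = np.linalg.eigh(block)
        block = (V * np.maximum(w, 1e-10)) @ V.T
    return block


# ---------------------------------------------------------------------------
# derived outputs


def summary_dor(fit: BivariateFit) -> tuple[float, tuple[float, float]]:
    """Summary odds ratio (intervention vs control) with 95% CI.

    log OR = mu_I - mu_C; in DTA terms this is the diagnostic odds ratio of
    the layout since logit specificity = -mu_C.
    """
    log_or = fit.mu_I - fit.mu_C
    V = np.asarray(fit.vcov_fixed)
    var = float(V[0, 0] + V[1, 1] - 2 * V[0, 1])
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.975)
    return math.exp(log_or), (math.exp(log_or - z * se), math.exp(log_or + z * se))


def _ellipse_from_cov(
    center_CI: tuple[float, float], C: np.ndarray, r2: float, n_points: int
) -> np.ndarray:
    eigs = np.linalg.eigvalsh(C)
    if eigs.min() < -1e-10:
        raise ValueError("ellipse covariance is not positive semi-definite")
    L = np.linalg.cholesky(C + 1e-12 * np.eye(2))
    t = np.linspace(0.0, 2 * math.pi, n_points)
    circ = np.column_stack([np.cos(t), np.sin(t)])
    path_logit = np.asarray(center_CI) + math.sqrt(r2) * circ @ L.T
    pts = expit(path_logit)
    pts[-1] = pts[0]  # closed
    return pts


def _radius2(level: float, scaling: str, k: int) -> float:
    if scaling == "chi2":
        return float(stats.chi2.ppf(level, df=2))
    if scaling == "f":
        if k <= 2:
            raise ValueError("F scaling needs k > 2")
        return float(2.0 * stats.f.ppf(level, 2, k - 2))
    raise ValueError(f"unknown ellipse scaling {scaling!r}")


def _perm_CI(M: np.ndarray) -> np.ndarray:
    """Reorder a (mu_I, mu_C) covariance to (control, intervention) axes."""
    P = np.array([[0.0, 1.0], [1.0, 0.0]])
    return P @ np.asarray(M) @ P.T


def confidence_ellipse(
    fit: BivariateFit, level: float = 0.95, scaling: str = "chi2", n_points: int = 200
) -> EllipsePath:
    """95% confidence region for the summary point, back-transformed.

    Built on the logit plane from the fixed-effect covariance and mapped
    pointwise through the inverse logit (so it is no longer elliptical on the
    incidence plane)."""
    C = _perm_CI(fit.vcov_fixed)
    pts = _ellipse_from_cov(
        (fit.mu_C, fit.mu_I), C, _radius2(level, scaling, fit.k), n_points
    )
    return EllipsePath(kind="confidence", level=level, points=pts)


def prediction_ellipse(
    fit: BivariateFit, level: float = 0.95, scaling: str = "chi2", n_points: int = 200
) -> EllipsePath:
    """95% prediction region for the arm pair of a new comparable study."""
    C = _perm_CI(np.asarray(fit.vcov_fixed) + fit.Sigma)
    pts = _ellipse_from_cov(
        (fit.mu_C, fit.mu_I), C, _radius2(level, scaling, fit.k), n_points
    )
    return EllipsePath(kind="prediction", level=level, points=pts)


def sroc_curve(
    fit: BivariateFit,
    x_grid: np.ndarray | None = None,
    x_range: tuple[float, float] | None = None,
    n_points: int = 100,
) -> SrocCurve:
    """Summary ROC curve as the conditional-mean line on the logit plane.

    eta_I(eta_C) = mu_I + rho (sigma_I / sigma_C) (eta_C - mu_C), evaluated
    over the control-incidence range and back-transformed. When sigma_C = 0
    the regression is undefined and a vertical reference through the summary
    point is returned with a warning.
    """
    if fit.sigma_C < 1e-8:
        warnings.warn(
            "sigma_C ~ 0: SROC curve undefined; returning vertical reference",
            stacklevel=2,
        )
        xc = float(expit(fit.mu_C))
        y = np.linspace(0.01, 0.99, n_points)
        pts = np.column_stack([np.full_like(y, xc), y])
        return SrocCurve(points=pts, parameterization_note="vertical reference (sigma_C=0)")
    if x_grid is None:
        if x_range is None:
            x_range = (
                float(expit(fit.mu_C - 2 * fit.sigma_C)),
                float(expit(fit.mu_C + 2 * fit.sigma_C)),
            )
        x_grid = np.linspace(x_range[0], x_range[1], n_points)
    x_grid = np.asarray(x_grid, dtype=float)
    eta_C = np.log(x_grid / (1 - x_grid))
    eta_I = fit.mu_I + fit.rho * (fit.sigma_I / fit.sigma_C) * (eta_C - fit.mu_C)
    pts = np.column_stack([x_grid, expit(eta_I)])
    return SrocCurve(
        points=pts,
        parameterization_note="conditional-mean regression of logit intervention "
        "incidence on logit control incidence",
    )
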