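"""Shared inverse-variance random-effects pooling core.

Both the logit-proportion (arm-based) and log-odds-ratio (contrast-based)
meta-analyses pool generic (y_i, v_i) effects:

* Cochran's Q with fixed-effect weights w_i = 1/v_i;
* tau^2 by restricted maximum likelihood (default) or the closed-form
  DerSimonian-Laird estimator, truncated at zero;
* I^2 = 100 * tau^2 / (tau^2 + s^2) with the Higgins-Thompson "typical"
  within-study variance s^2 = (k-1) * sum(w) / (sum(w)^2 - sum(w^2)), and
  H^2 = 1 / (1 - I^2/100), so the pair is internally consistent;
* summary and its standard error from random-effects weights 1/(v_i + tau^2);
* a 95% prediction interval y_hat +/- t_{k-2, 0.975} * sqrt(tau^2 + SE^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["PoolResult", "pool_effects", "dl_tau2"]


@dataclass(frozen=True)
class PoolResult:
    k: int
    mu: float          # pooled effect on the working (logit / log-OR) scale
    se: float
    ci95: tuple[float, float]
    pi95: tuple[float, float]  # (nan, nan) when k < 3
    Q: float
    df: int
    tau2: float
    I2: float          # percent
    H2: float


def dl_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """Closed-form DerSimonian-Laird tau^2, truncated at zero."""
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    Q = float(np.sum(w * (y - mu_fe) ** 2))
    df = len(y) - 1
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    if denom <= 0:
        return 0.0
    return max(0.0, (Q - df) / float(denom))


def _reml_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """REML tau^2 by bounded 1-D profile-likelihood maximisation."""

    def neg_restricted_ll(tau2: float) -> float:
        wi = 1.0 / (v + tau2)
        mu = np.sum(wi * y) / np.sum(wi)
        return 0.5 * float(
            np.sum(np.log(v + tau2)) + np.log(np.sum(wi)) + np.sum(wi * (y - mu) ** 2)
        )

    hi = max(10.0 * float(np.var(y)), 10.0 * float(np.max(v)), 1.0)
    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(0.0, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    return max(0.0, float(res.x))


def pool_effects(
    y: np.ndarray, v: np.ndarray, tau2_method: str = "REML"
) -> PoolResult:
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    k = len(y)
    if k < 2:
        raise ValueError("pooling requires at least 2 effects")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(v)):
        bad = int(np.argmax(~(np.isfinite(y) & np.isfinite(v))))
        raise ValueError(f"non-finite effect at position {bad}")
    if np.any(v <= 0):
        raise ValueError("within-study variances must be positive")

    w = 1.0 / v
    mu_fe = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - mu_fe) ** 2))
    df = k - 1

    if tau2_method.upper() == "REML":
        tau2 = _reml_tau2(y, v)
    elif tau2_method.upper() == "DL":
        tau2 = dl_tau2(y, v)
    else:
        raise ValueError(f"unknown tau2 method {tau2_method!r}")

    s2 = df * np.sum(w) / (np.sum(w) ** 2 - np.sum(w**2))
    I2 = 100.0 * tau2 / (tau2 + s2)
    H2 = 1.0 / (1.0 - I2 / 100.0)

    w_re = 1.0 / (v + tau2)
    mu = float(np.sum(w_re * y) / np.sum(w_re))
    se = float(np.sqrt(1.0 / np.sum(w_re)))
    z = stats.norm.ppf(0.975)
    ci = (mu - z * se, mu + z * se)
    if k >= 3:
        t = stats.t.ppf(0.975, df=k - 2)
        half = t * np.sqrt(tau2 + se**2)
        pi = (mu - half, mu + half)
    else:
        pi = (float("nan"), float("nan"))

    return PoolResult(
        k=k, mu=mu, se=se, ci95=ci, pi95=pi,
        Q=Q, df=df, tau2=float(tau2), I2=float(I2), H2=float(H2),
    )
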