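"""Dispersal kernel mean functions, count likelihoods, ML fitting and AIC.

Two kernel families describe the decline of expected settler / larval counts
R with distance D from the source:

    exponential:  R(D) = R0 * exp(beta * D)
    power law:    R(D) = R1 * D ** gamma          (D > 0)

Both are log-linear — ``log R = log R0 + beta D`` and
``log R = log R1 + gamma log D`` — so each is fit as a log-link count GLM with
predictor D or log D, under Poisson or negative-binomial (NB2: variance
mu + mu^2/theta) errors. The negative-binomial size theta is estimated
jointly by maximum likelihood. Models are compared by AIC with k = 2
(Poisson) or k = 3 (negative binomial) parameters.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import gammaln
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.discrete.discrete_model import NegativeBinomial
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "mean_exponential",
    "mean_power",
    "kernel_mean",
    "count_log_likelihood",
    "DispersalKernel",
    "KernelFit",
    "fit_kernel",
    "compare_models",
]

_Z975 = float(stats.norm.ppf(0.975))

FAMILIES = ("exponential", "power")
ERROR_FAMILIES = ("poisson", "negbin")


def mean_exponential(r0: float, beta: float, distance) -> np.ndarray | float:
    """Expected count R0 * exp(beta * D)."""
    if r0 <= 0:
        raise ValueError("R0 must be > 0")
    return r0 * np.exp(beta * np.asarray(distance, dtype=float))


def mean_power(r1: float, gamma: float, distance) -> np.ndarray | float:
    """Expected count R1 * D**gamma; undefined at D <= 0."""
    if r1 <= 0:
        raise ValueError("R1 must be > 0")
    d = np.asarray(distance, dtype=float)
    if np.any(d <= 0):
        raise ValueError("power-law kernel requires all distances > 0")
    return r1 * d**gamma


def kernel_mean(family: str, intercept: float, slope: float, distance):
    if family == "exponential":
        return mean_exponential(intercept, slope, distance)
    if family == "power":
        return mean_power(intercept, slope, distance)
    raise ValueError(f"unknown kernel family {family!r}")


def _predictor(family: str, distances: np.ndarray) -> np.ndarray:
    if family == "exponential":
        return distances
    if family == "power":
        if np.any(distances <= 0):
            raise ValueError("power-law kernel requires all distances > 0")
        return np.log(distances)
    raise ValueError(f"unknown kernel family {family!r}")


def count_log_likelihood(
    counts,
    distances,
    family: str,
    error_family: str,
    intercept: float,
    slope: float,
    dispersion: float | None = None,
) -> float:
    """Log-likelihood of counts under a kernel-mean count model.

    Sum over observations of the Poisson log-pmf at mean mu(D), or the
    negative-binomial (mean mu, size theta) log-pmf when
    ``error_family="negbin"``.
    """
    y = np.asarray(counts)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be nonnegative integers")
    d = np.asarray(distances, dtype=float)
    mu = np.asarray(kernel_mean(family, intercept, slope, d), dtype=float)
    if error_family == "poisson":
        return float(np.sum(stats.poisson.logpmf(y, mu)))
    if error_family == "negbin":
        if dispersion is None or dispersion <= 0:
            raise ValueError("negbin error family needs dispersion theta > 0")
        theta = float(dispersion)
        return float(np.sum(stats.nbinom.logpmf(y, theta, theta / (theta + mu))))
    raise ValueError(f"unknown error family {error_family!r}")


class KernelFitError(RuntimeError):
    """Maximum-likelihood fitting failed to converge."""


def _neg_loglik_linear(
    params: np.ndarray, y: np.ndarray, x: np.ndarray, error_family: str
) -> float:
    """Negative log-likelihood on the working scale (b0, b1[, log theta])."""
    eta = params[0] + params[1] * x
    if np.any(eta > 500):
        return np.inf
    mu = np.exp(eta)
    if error_family == "poisson":
        ll = np.sum(y * eta - mu - gammaln(y + 1))
    else:
        theta = np.exp(params[2])
        ll = np.sum(
            gammaln(y + theta)
            - gammaln(theta)
            - gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    return -ll if np.isfinite(ll) else np.inf


def _direct_ml(
    y: np.ndarray, x: np.ndarray, error_family: str, start: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Direct likelihood maximisation with numerical Wald SEs (fallback path)."""
    res = optimize.minimize(
        _neg_loglik_linear,
        start,
        args=(y, x, error_family),
        method="Nelder-Mead",
        options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-10},
    )
    res = optimize.minimize(
        _neg_loglik_linear,
        res.x,
        args=(y, x, error_family),
        method="BFGS",
        options={"maxiter": 1000},
    )
    hess = approx_hess1(res.x, _neg_loglik_linear, args=(y, x, error_family))
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full_like(res.x, np.nan)
    return res.x, se, -float(res.fun)


class DispersalKernel(RegressorMixin, BaseEstimator):
    """Maximum-likelihood dispersal-kernel count regression.

    A log-link count GLM of observed counts on distance from the source
    (exponential family) or log distance (power family), with Poisson or
    jointly-estimated negative-binomial (NB2) errors.

    Parameters
    ----------
    family : {"exponential", "power"}
        Kernel mean function.
    error_family : {"poisson", "negbin"}
        Count error distribution; "negbin" estimates the size theta by ML.

    Attributes
    ----------
    intercept_ : float
        Kernel intercept on the natural scale: R0 (expected count at D = 0,
        exponential) or R1 (expected count at D = 1 km, power).
    slope_ : float
        Decline rate beta (per km, exponential) or power exponent gamma.
    dispersion_ : float or None
        Estimated negative-binomial size theta; None under Poisson errors.
    intercept_ci_, slope_ci_ : tuple of float
        95% Wald intervals; the intercept interval is computed on the linear
        scale and exponentiated.
    log_likelihood_, aic_ : float
        Maximised log-likelihood and AIC = 2k - 2 logL with k = 2 (Poisson)
        or 3 (negbin).
    """

    def __init__(self, family: str = "power", error_family: str = "negbin"):
        self.family = family
        self.error_family = error_family

    def _validate(self, X, y) -> tuple[np.ndarray, np.ndarray]:
        d = np.asarray(X, dtype=float)
        if d.ndim == 2:
            if d.shape[1] != 1:
                raise ValueError("X must be distances: shape (n,) or (n, 1)")
            d = d[:, 0]
        y = np.asarray(y)
        if d.shape != y.shape:
            raise ValueError("distances and counts must have the same length")
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError("counts must be nonnegative integers")
        if not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite")
        if len(np.unique(d)) < 3:
            raise ValueError("need counts at >= 3 distinct distances")
        if not np.any(y > 0):
            raise ValueError("all counts are zero; kernel is not identifiable")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.error_family not in ERROR_FAMILIES:
            raise ValueError(f"unknown error family {self.error_family!r}")
        return d, y.astype(np.int64)

    def fit(self, X, y):
        d, y = self._validate(X, y)
        x = _predictor(self.family, d)
        exog = sm.add_constant(x)
        method = "statsmodels"
        try:
            if self.error_family == "poisson":
                res = sm.GLM(y, exog, family=sm.families.Poisson()).fit()
                params = np.asarray(res.params, dtype=float)
                se = np.asarray(res.bse, dtype=float)
                llf = float(res.llf)
                theta = None
                se_logtheta = None
            else:
                import warnings

                start_pois = sm.GLM(y, exog, family=sm.families.Poisson()).fit().params
                mod = NegativeBinomial(y, exog, loglike_method="nb2")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = mod.fit(
                        start_params=np.append(start_pois, 0.5), disp=0, maxiter=500
                    )
                if not res.mle_retvals.get("converged", True):
                    raise KernelFitError("negative-binomial ML did not converge")
                raw = np.asarray(res.params, dtype=float)
                bse = np.asarray(res.bse, dtype=float)
                alpha = raw[2]
                if alpha <= 0 or not np.all(np.isfinite(bse[:2])):
                    raise KernelFitError("degenerate negative-binomial solution")
                params, se = raw[:2], bse[:2]
                theta = 1.0 / alpha
                # delta method: se(log theta) = se(alpha) / alpha
                se_logtheta = float(bse[2] / alpha) if np.isfinite(bse[2]) else None
                llf = float(res.llf)
        except (KernelFitError, np.linalg.LinAlgError, ValueError, RuntimeError):
            # robustness path: direct likelihood maximisation
            method = "direct"
            start = np.array([np.log(max(y.mean(), 0.5)), -0.1])
            if self.error_family == "negbin":
                start = np.append(start, 0.0)
            sol, ses, llf = _direct_ml(y, x, self.error_family, start)
            params, se = sol[:2], ses[:2]
            if self.error_family == "negbin":
                theta = float(np.exp(sol[2]))
                se_logtheta = float(ses[2])
            else:
                theta = None
                se_logtheta = None
        if not np.all(np.isfinite(params)):
            raise KernelFitError(
                f"{self.family}/{self.error_family} fit produced non-finite "
                f"estimates (method={method}): params={params}"
            )
        k = 2 if self.error_family == "poisson" else 3
        self.linear_params_ = params.copy()
        self.linear_se_ = se.copy()
        self.dispersion_ = theta
        self.dispersion_log_se_ = se_logtheta
        self.intercept_ = float(np.exp(params[0]))
        self.slope_ = float(params[1])
        self.intercept_ci_ = (
            float(np.exp(params[0] - _Z975 * se[0])),
            float(np.exp(params[0] + _Z975 * se[0])),
        )
        self.slope_ci_ = (
            float(params[1] - _Z975 * se[1]),
            float(params[1] + _Z975 * se[1]),
        )
        self.log_likelihood_ = float(llf)
        self.k_params_ = k
        self.aic_ = 2.0 * k - 2.0 * self.log_likelihood_
        self.n_obs_ = int(len(y))
        self.fit_method_ = method
        self._data_signature = hashlib.sha1(
            d.tobytes() + y.tobytes()
        ).hexdigest()
        return self

    def predict(self, X) -> np.ndarray:
        d = np.asarray(X, dtype=float)
        if d.ndim == 2:
            d = d[:, 0]
        return np.asarray(
            kernel_mean(self.family, self.intercept_, self.slope_, d), dtype=float
        )

    def to_fit(self) -> "KernelFit":
        return KernelFit(
            family=self.family,
            error_family=self.error_family,
            intercept=self.intercept_,
            intercept_ci=self.intercept_ci_,
            slope=self.slope_,
            slope_ci=self.slope_ci_,
            dispersion=self.dispersion_,
            log_likelihood=self.log_likelihood_,
            aic=self.aic_,
            n_obs=self.n_obs_,
            linear_params=tuple(self.linear_params_),
            linear_se=tuple(self.linear_se_),
            dispersion_log_se=self.dispersion_log_se_,
            data_signature=self._data_signature,
        )


@dataclass(frozen=True)
class KernelFit:
    """Result of a maximum-likelihood kernel fit."""

    family: str
    error_family: str
    intercept: float
    intercept_ci: tuple[float, float]
    slope: float
    slope_ci: tuple[float, float]
    dispersion: float | None
    log_likelihood: float
    aic: float
    n_obs: int
    linear_params: tuple[float, ...]
    linear_se: tuple[float, ...]
    dispersion_log_se: float | None = None
    data_signature: str | None = None

    @property
    def k_params(self) -> int:
        return 2 if self.error_family == "poisson" else 3

    def mean_at(self, distance):
        return kernel_mean(self.family, self.intercept, self.slope, distance)


def fit_kernel(
    distances, counts, family: str = "power", error_family: str = "negbin"
) -> KernelFit:
    """Fit one kernel family / error family combination; see DispersalKernel."""
    est = DispersalKernel(family=family, error_family=error_family)
    est.fit(np.asarray(distances, dtype=float), counts)
    return est.to_fit()


def compare_models(fits: list[KernelFit]):
    """Rank fits of the same data by AIC.

    Returns a DataFrame in ascending-AIC order with ``delta_aic`` relative to
    the best model and a ``best`` flag; ties keep declaration order.
    """
    import pandas as pd

    if len(fits) < 2:
        raise ValueError("need >= 2 fits to compare")
    sigs = {f.data_signature for f in fits}
    if len(sigs) > 1:
        raise ValueError("fits were made on different observation sets")
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aic, i))
    best_aic = fits[order[0]].aic
    rows = [
        {
            "rank": r + 1,
            "family": fits[i].family,
            "error_family": fits[i].error_family,
            "aic": fits[i].aic,
            "delta_aic": fits[i].aic - best_aic,
            "best": r == 0,
        }
        for r, i in enumerate(order)
    ]
    return pd.DataFrame(rows)
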