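"""Parametric empirical Bayes over first-level posteriors.

Second level of the hierarchy: subject-level parameter posteriors
(means + covariances from model inversion) are modelled with a group GLM

    theta_i^(1) = X_i theta^(2) + eps_i^(2),    eps ~ N(0, Sigma_b),

where X has an intercept column of ones encoding commonalities and contrast
regressors of interest, and Sigma_b is the between-subject (random-effects)
covariance, parameterized as a single variance scale estimated by
free-energy (marginal-likelihood) optimization.  Precision weighting means
subjects with more uncertain first-level estimates contribute less.

Evidence for individual group effects is assessed by Bayesian model
reduction: the posterior probability of an effect is the sigmoid of the
free-energy difference between the model with the effect free and the model
with it pruned to zero.  Effect size is assessed by leave-one-out
cross-validation: a group model fitted without one subject predicts that
subject's covariate from its parameters; predictive accuracy is the Pearson
correlation between true and predicted covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "PEB",
    "peb_fit",
    "posterior_probability",
    "loo_cv",
    "contrast_report",
    "gaussian_bmr",
    "LOOResult",
]


def gaussian_bmr(
    mu0: np.ndarray,
    s0: np.ndarray,
    mu: np.ndarray,
    s: np.ndarray,
    mu0r: np.ndarray,
    s0r: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Bayesian model reduction for Gaussian prior/posterior pairs.

    Given a full prior N(mu0, s0) with posterior N(mu, s), returns the
    change in log evidence (reduced minus full) obtained by replacing the
    prior with N(mu0r, s0r), together with the reduced posterior mean and
    covariance.  The likelihood implied by the full pair is held fixed.
    """
    p0 = np.linalg.inv(s0)
    p = np.linalg.inv(s)
    p0r = np.linalg.inv(s0r)
    pr = p + p0r - p0
    sr = np.linalg.inv(pr)
    mur = sr @ (p @ mu + p0r @ mu0r - p0 @ mu0)
    _, ld_p0r = np.linalg.slogdet(p0r)
    _, ld_p0 = np.linalg.slogdet(p0)
    _, ld_pr = np.linalg.slogdet(pr)
    _, ld_p = np.linalg.slogdet(p)
    d_f = 0.5 * (ld_p0r - ld_pr - ld_p0 + ld_p) - 0.5 * (
        mu0r @ p0r @ mu0r - mur @ pr @ mur - mu0 @ p0 @ mu0 + mu @ p @ mu
    )
    return float(d_f), mur, 0.5 * (sr + sr.T)


@dataclass
class LOOResult:
    r: float
    p_value: float
    predictions: np.ndarray
    covariate: np.ndarray


class PEB(BaseEstimator):
    """Hierarchical Gaussian model over stacked first-level posteriors.

    Parameters
    ----------
    theta2_prior_var : float
        Prior variance of each second-level parameter (prior mean zero).
    between_base_var : float
        Base between-subject variance; the estimated scale multiplies it by
        exp(gamma).
    gamma_prior_var : float
        Variance of the Gaussian prior on the log variance-scale gamma.

    After ``fit(means, covs, X)``:

    Attributes
    ----------
    theta2_mean_ : (k, p) second-level posterior means (regressor x param)
    theta2_cov_ : (k p, k p) posterior covariance (vec ordering: regressor
        index major, parameter index minor)
    gamma_, between_var_ : estimated log scale and between-subject variance
    free_energy_ : marginal log likelihood at the optimum (incl. gamma prior)
    """

    def __init__(
        self,
        theta2_prior_var: float = 1.0,
        between_base_var: float = 1.0 / 16,
        gamma_prior_var: float = 4.0,
        gamma_bounds: tuple[float, float] = (-8.0, 8.0),
        param_names: tuple[str, ...] | None = None,
    ):
        self.theta2_prior_var = theta2_prior_var
        self.between_base_var = between_base_var
        self.gamma_prior_var = gamma_prior_var
        self.gamma_bounds = gamma_bounds
        self.param_names = param_names

    # -- internals ---------------------------------------------------------

    def _design(self, x: np.ndarray, p: int) -> np.ndarray:
        """Stacked design D: row block i is kron(x_i, I_p); shape (np, kp)."""
        n, k = x.shape
        d = np.zeros((n * p, k * p))
        eye = np.eye(p)
        for i in range(n):
            d[i * p : (i + 1) * p] = np.kron(x[i], eye)
        return d

    def _marginal_f(
        self, gamma: float, means: np.ndarray, covs: np.ndarray, x: np.ndarray
    ) -> float:
        """Log evidence of the stacked means under the hierarchical model."""
        n, p = means.shape
        sb = np.exp(gamma) * self.between_base_var * np.eye(p)
        d = self._design(x, p)
        big = d @ (self.theta2_prior_var * np.eye(d.shape[1])) @ d.T
        for i in range(n):
            big[i * p : (i + 1) * p, i * p : (i + 1) * p] += covs[i] + sb
        y = means.ravel()
        sign, logdet = np.linalg.slogdet(big)
        if sign <= 0:
            return -np.inf
        alpha = np.linalg.solve(big, y)
        ll = -0.5 * (y @ alpha + logdet + y.size * np.log(2 * np.pi))
        ll += -0.5 * gamma**2 / self.gamma_prior_var - 0.5 * np.log(
            2 * np.pi * self.gamma_prior_var
        )
        return float(ll)

    # -- fitting -----------------------------------------------------------

    def fit(self, means: np.ndarray, covs: np.ndarray, X: np.ndarray):
        means = np.asarray(means, dtype=float)
        covs = np.asarray(covs, dtype=float)
        x = np.atleast_2d(np.asarray(X, dtype=float))
        n, p = means.shape
        if n < 2:
            raise ValueError("need at least 2 subjects")
        if x.shape[0] != n:
            raise ValueError("design matrix rows must match subjects")
        if covs.shape != (n, p, p):
            raise ValueError("mismatched first-level covariance stack")
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("design matrix is rank deficient")
        k = x.shape[1]

        res = optimize.minimize_scalar(
            lambda g: -self._marginal_f(g, means, covs, x),
            bounds=self.gamma_bounds,
            method="bounded",
            options={"xatol": 1e-4},
        )
        self.gamma_ = float(res.x)
        self.between_var_ = float(
            np.exp(self.gamma_) * self.between_base_var
        )
        self.free_energy_ = float(-res.fun)

        sb = self.between_var_ * np.eye(p)
        prec = np.eye(k * p) / self.theta2_prior_var
        rhs = np.zeros(k * p)
        self._w = np.empty((n, p, p))
        for i in range(n):
            w = np.linalg.inv(covs[i] + sb)
            self._w[i] = w
            prec += np.kron(np.outer(x[i], x[i]), w)
            rhs += np.kron(x[i], w @ means[i])
        cov2 = np.linalg.inv(prec)
        mean2 = cov2 @ rhs
        self.theta2_cov_ = 0.5 * (cov2 + cov2.T)
        self.theta2_mean_ = mean2.reshape(k, p)
        self._prior_cov2 = self.theta2_prior_var * np.eye(k * p)
        self.n_subjects_ = n
        self.n_params_ = p
        self.n_regressors_ = k
        self.X_ = x
        self.means_ = means
        self.covs_ = covs
        return self

    # -- inference ---------------------------------------------------------

    def posterior_probability(self, param: int, regressor: int = 1) -> float:
        """Pp that the (regressor, param) effect is present.

        Bayesian model reduction prunes the single second-level parameter
        to zero (reduced prior variance 1e-8); Pp is the sigmoid of the
        free-energy difference full - reduced.
        """
        kp = self.n_regressors_ * self.n_params_
        idx = regressor * self.n_params_ + param
        mu0 = np.zeros(kp)
        s0 = self._prior_cov2
        s0r = s0.copy()
        s0r[idx, idx] = 1e-8
        d_f, _, _ = gaussian_bmr(
            mu0, s0, self.theta2_mean_.ravel(), self.theta2_cov_, mu0, s0r
        )
        # d_f = F_reduced - F_full; evidence for presence is -d_f
        return float(1.0 / (1.0 + np.exp(d_f)))

    def effect_table(self, regressor: int = 1) -> pd.DataFrame:
        names = self.param_names or tuple(
            f"param_{j}" for j in range(self.n_params_)
        )
        rows = []
        for j in range(self.n_params_):
            mean = float(self.theta2_mean_[regressor, j])
            idx = regressor * self.n_params_ + j
            sd = float(np.sqrt(self.theta2_cov_[idx, idx]))
            rows.append(
                {
                    "parameter": names[j],
                    "regressor": regressor,
                    "posterior_mean": mean,
                    "posterior_sd": sd,
                    "sign": int(np.sign(mean)),
                    "pp": self.posterior_probability(j, regressor),
                }
            )
        return pd.DataFrame(rows)


def peb_fit(
    means: np.ndarray,
    covs: np.ndarray,
    X: np.ndarray,
    param_names: tuple[str, ...] | None = None,
    **kwargs,
) -> PEB:
    """Fit the hierarchical group model (thin wrapper over :class:`PEB`)."""
    return PEB(param_names=param_names, **kwargs).fit(means, covs, X)


def posterior_probability(model: PEB, param: int, regressor: int = 1) -> float:
    return model.posterior_probability(param, regressor)


def loo_cv(
    means: np.ndarray,
    covs: np.ndarray,
    X: np.ndarray,
    regressor: int = 1,
    **kwargs,
) -> LOOResult:
    """Leave-one-out predictive accuracy of a group covariate.

    For each left-out subject, a PEB model fitted to the remaining subjects
    supplies group effects; the left-out covariate is then the
    precision-weighted least-squares projection of that subject's
    (common-effect-corrected) parameters onto the contrast effect.  Returns
    the Pearson correlation between true and predicted covariates with its
    two-sided p-value.
    """
    means = np.asarray(means, dtype=float)
    covs = np.asarray(covs, dtype=float)
    x = np.atleast_2d(np.asarray(X, dtype=float))
    n = means.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects for cross-validation")
    covariate = x[:, regressor]
    if np.ptp(covariate) == 0:
        raise ValueError("constant covariate cannot be predicted")
    other = [c for c in range(x.shape[1]) if c != regressor]
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        model = PEB(**kwargs).fit(means[keep], covs[keep], x[keep])
        w = np.linalg.inv(covs[i] + model.between_var_ * np.eye(means.shape[1]))
        resid = means[i] - x[i, other] @ model.theta2_mean_[other]
        eff = model.theta2_mean_[regressor]
        denom = eff @ w @ eff
        preds[i] = (eff @ w @ resid) / denom if denom > 0 else 0.0
    result = stats.pearsonr(covariate, preds)
    return LOOResult(
        float(result.statistic), float(result.pvalue), preds, covariate.copy()
    )


def contrast_report(
    model: PEB,
    loo_result: LOOResult | None = None,
    threshold_pp: float = 0.95,
    loo_alpha: float = 0.05,
    regressor: int = 1,
    contrast_label: str = "",
) -> pd.DataFrame:
    """Connections passing the evidence gate (and the LOO gate when given).

    Returns one row per second-level effect with posterior mean, sign and
    Pp; the ``flagged`` column marks effects with Pp above threshold and,
    when a LOO result is supplied, group-level predictive p below alpha.
    """
    table = model.effect_table(regressor)
    table["contrast"] = contrast_label
    gate = table["pp"] > threshold_pp
    if loo_result is not None:
        table["loo_r"] = loo_result.r
        table["loo_p"] = loo_result.p_value
        gate = gate & (loo_result.p_value < loo_alpha)
    table["flagged"] = gate
    return table
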