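"""Three-component mixture model of continuous-report working-memory errors.

A report of a remembered feature (here: angular location) is modelled as
coming from one of three sources: a Von Mises distribution centred on the
*target* item, a Von Mises centred on one of the *non-target* items (a swap),
or a uniform *guess*:

    p(r | t, nt_1..m) = (1 - beta - gamma) * VM(r - t; kappa)
                        + gamma / (2 pi)
                        + beta / m * sum_i VM(r - nt_i; kappa)

with gamma the guess probability, beta the swap probability and kappa the
shared Von Mises concentration.  Maximum-likelihood estimates are obtained by
expectation-maximisation; per-report posterior responsibilities over the
three components drive trial labelling: a trial is *high accuracy* when the
target responsibility exceeds 0.9 in all three reports, a *swap* when the
pooled non-target responsibility exceeds 0.7 in at least one report, and
*low accuracy* otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike
from scipy import optimize, special
from sklearn.base import BaseEstimator, DensityMixin
from sklearn.utils import check_random_state

__all__ = [
    "wrap_angle",
    "kappa_to_sigma",
    "sigma_to_kappa",
    "vonmises_density",
    "mixture_density",
    "VonMisesMixture",
    "fit_mixture",
    "responsibilities",
    "classify_trials",
    "behavior_summary",
    "HIGH_ACCURACY",
    "LOW_ACCURACY",
    "SWAP",
]

HIGH_ACCURACY = "high_accuracy"
LOW_ACCURACY = "low_accuracy"
SWAP = "swap"

#: p(target) threshold that all three reports must exceed for "high accuracy"
TARGET_THRESHOLD = 0.9
#: pooled p(non-target) threshold that at least one report must exceed for "swap"
NONTARGET_THRESHOLD = 0.7


def wrap_angle(x: ArrayLike) -> np.ndarray:
    """Wrap angles (radians) to the interval [-pi, pi)."""
    return np.mod(np.asarray(x, dtype=float) + np.pi, 2.0 * np.pi) - np.pi


def _mean_resultant_length(kappa: ArrayLike) -> np.ndarray:
    """R(kappa) = I1(kappa) / I0(kappa), computed with scaled Bessels."""
    kappa = np.asarray(kappa, dtype=float)
    return special.i1e(kappa) / special.i0e(kappa)


def kappa_to_sigma(kappa: ArrayLike) -> np.ndarray:
    """Circular standard deviation sigma = sqrt(-2 ln R(kappa)), radians.

    kappa = 0 gives the uniform distribution, for which sigma is infinite.
    """
    r = _mean_resultant_length(kappa)
    with np.errstate(divide="ignore"):
        return np.sqrt(-2.0 * np.log(r))


def sigma_to_kappa(sigma: float) -> float:
    """Invert :func:`kappa_to_sigma` numerically (sigma in radians, > 0)."""
    if sigma <= 0:
        raise ValueError("circular SD must be positive")
    target_r = np.exp(-0.5 * sigma**2)
    if target_r >= 1.0 - 1e-12:
        raise ValueError("sigma too small to invert")
    f = lambda k: _mean_resultant_length(k) - target_r
    lo, hi = 1e-8, 2.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e8:
            raise ValueError("sigma too small to invert")
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def vonmises_density(x: ArrayLike, kappa: float) -> np.ndarray:
    """Von Mises density with zero mean and concentration ``kappa``.

    Evaluated as exp(kappa (cos x - 1)) / (2 pi I0e(kappa)) so that large
    concentrations do not overflow; kappa = 0 reduces to the circular
    uniform density 1 / (2 pi).
    """
    if kappa < 0:
        raise ValueError("Von Mises concentration must be >= 0")
    x = np.asarray(x, dtype=float)
    return np.exp(kappa * (np.cos(x) - 1.0)) / (2.0 * np.pi * special.i0e(kappa))


def _component_densities(
    target_err: np.ndarray, nontarget_err: np.ndarray, kappa: float
) -> tuple[np.ndarray, np.ndarray]:
    """Density of the target component and the pooled non-target mean density."""
    d_target = vonmises_density(target_err, kappa)
    d_nontarget = vonmises_density(nontarget_err, kappa).mean(axis=1)
    return d_target, d_nontarget


def mixture_density(
    target_err: ArrayLike,
    nontarget_err: ArrayLike,
    kappa: float,
    gamma: float,
    beta: float,
) -> np.ndarray:
    """Mixture density of a report given its angular deviations.

    Parameters
    ----------
    target_err : array, shape (n,)
        Wrapped deviation report - target.
    nontarget_err : array, shape (n, m)
        Wrapped deviations report - nontarget_i.
    """
    _validate_weights(gamma, beta)
    target_err = np.atleast_1d(np.asarray(target_err, dtype=float))
    nontarget_err = np.atleast_2d(np.asarray(nontarget_err, dtype=float))
    d_t, d_nt = _component_densities(target_err, nontarget_err, kappa)
    return (1.0 - beta - gamma) * d_t + gamma / (2.0 * np.pi) + beta * d_nt


def _validate_weights(gamma: float, beta: float) -> None:
    if gamma < 0 or beta < 0 or gamma + beta > 1.0 + 1e-12:
        raise ValueError("need gamma >= 0, beta >= 0, gamma + beta <= 1")


def _extract_errors(reports: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Wrapped (report - target) and (report - nontarget_i) from a report table.

    The table needs columns ``target``, ``report`` and either ``nontargets``
    (sequence-valued) or columns ``nontarget_1 .. nontarget_m``.
    """
    report = np.asarray(reports["report"], dtype=float)
    target = np.asarray(reports["target"], dtype=float)
    if "nontargets" in reports.columns:
        nts = np.stack([np.asarray(v, dtype=float) for v in reports["nontargets"]])
    else:
        cols = sorted(c for c in reports.columns if c.startswith("nontarget_"))
        if not cols:
            raise ValueError("no non-target columns found")
        nts = reports[cols].to_numpy(dtype=float)
    return wrap_angle(report - target), wrap_angle(report[:, None] - nts)


class VonMisesMixture(DensityMixin, BaseEstimator):
    """Target / non-target / guess mixture fitted by expectation-maximisation.

    Parameters
    ----------
    n_restarts : int
        EM restarts from dispersed starting points; the best (highest
        log-likelihood) solution is kept.
    max_iter, tol : int, float
        EM stopping rule: relative log-likelihood change below ``tol``.
    min_reports : int
        Minimum number of reports required to fit.
    random_state : int | None
        Seeds the restart dispersion.

    Attributes
    ----------
    kappa_, sigma_, gamma_, beta_ : float
        ML estimates (sigma_ is the circular SD implied by kappa_, radians).
    log_likelihood_ : float
        Total data log-likelihood at the optimum.
    boundary_ : bool
        True when the solution sits on the parameter boundary (degenerate
        data such as all-identical reports).
    """

    def __init__(
        self,
        n_restarts: int = 5,
        max_iter: int = 500,
        tol: float = 1e-9,
        min_reports: int = 20,
        kappa_max: float = 1e4,
        random_state: int | None = None,
    ):
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.min_reports = min_reports
        self.kappa_max = kappa_max
        self.random_state = random_state

    # -- EM machinery ------------------------------------------------------

    def _e_step(
        self,
        target_err: np.ndarray,
        nontarget_err: np.ndarray,
        kappa: float,
        gamma: float,
        beta: float,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        """Responsibilities (target, guess, pooled non-target) and log-lik."""
        d_t, d_nt = _component_densities(target_err, nontarget_err, kappa)
        c_t = (1.0 - beta - gamma) * d_t
        c_g = np.full_like(d_t, gamma / (2.0 * np.pi))
        c_nt = beta * d_nt
        total = c_t + c_g + c_nt
        total = np.maximum(total, 1e-300)
        ll = float(np.log(total).sum())
        return c_t / total, c_g / total, c_nt / total, ll

    def _update_kappa(
        self,
        target_err: np.ndarray,
        nontarget_err: np.ndarray,
        r_t: np.ndarray,
        r_nt: np.ndarray,
        kappa: float,
    ) -> float:
        """Weighted mean-resultant-length update, inverted numerically.

        Non-target responsibility is split across the m non-targets in
        proportion to their densities at the current kappa.
        """
        d_each = vonmises_density(nontarget_err, kappa)
        d_sum = np.maximum(d_each.sum(axis=1, keepdims=True), 1e-300)
        w_each = r_nt[:, None] * d_each / d_sum
        w_total = r_t.sum() + w_each.sum()
        if w_total < 1e-12:
            return 0.0
        c = (r_t * np.cos(target_err)).sum() + (w_each * np.cos(nontarget_err)).sum()
        s = (r_t * np.sin(target_err)).sum() + (w_each * np.sin(nontarget_err)).sum()
        rbar = min(np.hypot(c, s) / w_total, 1.0 - 1e-12)
        f = lambda k: _mean_resultant_length(k) - rbar
        if f(self.kappa_max) < 0:
            return float(self.kappa_max)
        return float(optimize.brentq(f, 1e-10, self.kappa_max, xtol=1e-10))

    def _run_em(
        self,
        target_err: np.ndarray,
        nontarget_err: np.ndarray,
        start: tuple[float, float, float],
    ) -> tuple[float, float, float, float, int]:
        kappa, gamma, beta = start
        ll_prev = -np.inf
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            r_t, r_g, r_nt, ll = self._e_step(
                target_err, nontarget_err, kappa, gamma, beta
            )
            gamma = float(r_g.mean())
            beta = float(r_nt.mean())
            kappa = self._update_kappa(target_err, nontarget_err, r_t, r_nt, kappa)
            if ll - ll_prev < self.tol * max(1.0, abs(ll)) and n_iter > 2:
                ll_prev = ll
                break
            ll_prev = ll
        return kappa, gamma, beta, ll_prev, n_iter

    # -- sklearn interface -------------------------------------------------

    def fit(self, X: pd.DataFrame | ArrayLike, y=None) -> "VonMisesMixture":
        """Fit the mixture to a table of reports.

        ``X`` is either a report table (columns ``target``, ``report`` and
        non-target columns, see :func:`fit_mixture`) or a plain array of
        shape (n, 1 + m) whose first column is the wrapped report-target
        deviation and remaining columns the report-nontarget deviations.
        """
        if isinstance(X, pd.DataFrame):
            target_err, nontarget_err = _extract_errors(X)
        else:
            X = np.asarray(X, dtype=float)
            target_err, nontarget_err = X[:, 0], X[:, 1:]
        if target_err.shape[0] < self.min_reports:
            raise ValueError(
                f"need at least {self.min_reports} reports, got {target_err.shape[0]}"
            )
        rng = check_random_state(self.random_state)

        starts = [(8.0, 0.1, 0.1)]
        for _ in range(self.n_restarts - 1):
            w = rng.dirichlet((2.0, 1.0, 1.0))
            starts.append((float(np.exp(rng.uniform(0.5, 3.5))), w[1], w[2]))

        best = None
        for start in starts:
            fitted = self._run_em(target_err, nontarget_err, start)
            if best is None or fitted[3] > best[3]:
                best = fitted
        kappa, gamma, beta, ll, n_iter = best

        self.kappa_ = kappa
        self.sigma_ = float(kappa_to_sigma(kappa))
        self.gamma_ = gamma
        self.beta_ = beta
        self.log_likelihood_ = ll
        self.n_iter_ = n_iter
        self.boundary_ = bool(
            kappa >= self.kappa_max * (1 - 1e-9)
            or min(gamma, beta, 1 - gamma - beta) < 1e-9
        )
        return self

    def responsibilities(self, X: pd.DataFrame | ArrayLike) -> np.ndarray:
        """Posterior component probabilities, shape (n, 3).

        Columns are (target, guess, pooled non-target); rows sum to one.
        """
        if isinstance(X, pd.DataFrame):
            target_err, nontarget_err = _extract_errors(X)
        else:
            X = np.asarray(X, dtype=float)
            target_err, nontarget_err = X[:, 0], X[:, 1:]
        r_t, r_g, r_nt, _ = self._e_step(
            target_err, nontarget_err, self.kappa_, self.gamma_, self.beta_
        )
        return np.column_stack([r_t, r_g, r_nt])

    def score(self, X, y=None) -> float:
        """Mean per-report log-likelihood."""
        if isinstance(X, pd.DataFrame):
            target_err, nontarget_err = _extract_errors(X)
        else:
            X = np.asarray(X, dtype=float)
            target_err, nontarget_err = X[:, 0], X[:, 1:]
        *_, ll = self._e_step(
            target_err, nontarget_err, self.kappa_, self.gamma_, self.beta_
        )
        return ll / target_err.shape[0]


def fit_mixture(
    reports: pd.DataFrame, random_state: int | None = 0, **kwargs
) -> VonMisesMixture:
    """Fit :class:`VonMisesMixture` to a report table (thin wrapper)."""
    return VonMisesMixture(random_state=random_state, **kwargs).fit(reports)


def responsibilities(reports: pd.DataFrame, model: VonMisesMixture) -> pd.DataFrame:
    """Per-report posterior component probabilities as a data frame."""
    resp = model.responsibilities(reports)
    out = reports.copy()
    out["p_target"] = resp[:, 0]
    out["p_guess"] = resp[:, 1]
    out["p_nontarget"] = resp[:, 2]
    return out


def classify_trials(
    resp: pd.DataFrame,
    target_threshold: float = TARGET_THRESHOLD,
    nontarget_threshold: float = NONTARGET_THRESHOLD,
    n_reports: int = 3,
) -> pd.DataFrame:
    """Label each trial high_accuracy / swap / low_accuracy from its reports.

    ``resp`` needs columns ``trial``, ``p_target``, ``p_nontarget``.  A trial
    is high accuracy when p_target exceeds the target threshold in *all*
    reports, else a swap when p_nontarget exceeds the non-target threshold in
    *at least one* report, else low accuracy.  Every trial must carry exactly
    ``n_reports`` reports.
    """
    counts = resp.groupby("trial").size()
    bad = counts[counts != n_reports]
    if len(bad):
        raise ValueError(
            f"trials without exactly {n_reports} reports: {list(bad.index[:5])}"
        )
    g = resp.groupby("trial")
    min_pt = g["p_target"].min()
    max_pnt = g["p_nontarget"].max()
    label = pd.Series(LOW_ACCURACY, index=min_pt.index, name="label")
    label[max_pnt > nontarget_threshold] = SWAP
    label[min_pt > target_threshold] = HIGH_ACCURACY
    return label.reset_index()


def behavior_summary(
    reports: pd.DataFrame, labels: pd.DataFrame
) -> pd.DataFrame:
    """Per-label trial proportions and mean absolute circular error (degrees)."""
    merged = reports.merge(labels, on="trial")
    err = np.abs(wrap_angle(merged["report"] - merged["target"]))
    merged = merged.assign(abs_error_deg=np.degrees(err))
    n_trials = labels["trial"].nunique()
    rows = []
    for label in (HIGH_ACCURACY, LOW_ACCURACY, SWAP):
        sub = merged[merged["label"] == label]
        rows.append(
            {
                "label": label,
                "n_trials": sub["trial"].nunique(),
                "proportion": sub["trial"].nunique() / n_trials,
                "mean_abs_error_deg": sub["abs_error_deg"].mean()
                if len(sub)
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
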