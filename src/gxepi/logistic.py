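"""Logistic regression by iteratively reweighted least squares.

One fitter serves both the interaction scan (unpenalized maximum likelihood,
Wald tests from the observed information) and, with a ridge penalty and a
penalty mask, the penalized engine in :mod:`gxepi.plr`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

MAX_ITER = 100
DEV_TOL = 1e-8
_SEPARATION_BETA = 25.0


@dataclass
class LogisticFit:
    beta: np.ndarray
    cov: np.ndarray | None
    deviance: float
    loglik: float
    edf: float
    converged: bool
    n_iter: int
    n_obs: int

    def wald_p(self, j: int) -> float:
        """Two-sided Wald p-value for coefficient j (NaN if unusable)."""
        from scipy import stats

        if not self.converged or self.cov is None:
            return float("nan")
        se = np.sqrt(self.cov[j, j])
        if not np.isfinite(se) or se == 0:
            return float("nan")
        z = self.beta[j] / se
        return float(2 * stats.norm.sf(abs(z)))


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: log(1+exp(eta)) via logaddexp
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(y: np.ndarray, X: np.ndarray,
                 lam: float = 0.0,
                 penalty_mask: np.ndarray | None = None) -> LogisticFit:
    """Fit a binary logistic model by IRLS.

    With ``lam > 0`` the objective is the penalized log-likelihood
    ``l(beta) - (lam/2) * ||beta[mask]||^2`` (intercept and covariates are
    left unpenalized via ``penalty_mask``).  Convergence is declared when the
    (penalized) deviance changes by less than 1e-8; 100 iterations or runaway
    coefficients mark the fit non-converged (separation), in which case the
    caller should treat test statistics as missing.

    Returns coefficients, observed-information covariance (ridge-adjusted when
    penalized), deviance (-2 log-likelihood, unpenalized), and the effective
    degrees of freedom trace[(X'WX + L)^-1 X'WX].
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    uy = np.unique(y)
    if not np.isin(uy, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    if uy.size < 2:
        raise ValueError("outcome has no variation")
    if penalty_mask is None:
        penalty_mask = np.ones(p)
        penalty_mask[0] = 0.0  # column 0 assumed intercept
    pen = lam * np.asarray(penalty_mask, dtype=float)
    Lam = np.diag(pen)

    beta = np.zeros(p)
    prev_obj = np.inf
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        H = XtW @ X + Lam
        try:
            beta = np.linalg.solve(H, XtW @ z)
        except np.linalg.LinAlgError:
            return LogisticFit(beta, None, np.nan, np.nan, np.nan, False, it, n)
        obj = -2 * _loglik(y, X @ beta) + pen @ beta**2
        if abs(prev_obj - obj) < DEV_TOL:
            converged = True
            break
        prev_obj = obj
    if np.abs(beta).max() > _SEPARATION_BETA or not np.isfinite(beta).all():
        converged = False

    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    XtWX = (X.T * w) @ X
    H = XtWX + Lam
    ll = _loglik(y, eta)
    try:
        Hinv = np.linalg.inv(H)
        cov = Hinv if lam == 0 else Hinv @ XtWX @ Hinv
        edf = float(np.trace(Hinv @ XtWX))
    except np.linalg.LinAlgError:
        cov, edf = None, float("nan")
        converged = False
    return LogisticFit(
        beta=beta, cov=cov, deviance=-2 * ll, loglik=ll, edf=edf,
        converged=converged, n_iter=it, n_obs=n,
    )
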