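"""Non-dynamic regression baselines for the dosage-to-count problem.

Two static regressions of the daily count on the daily dosages, used as
reference points for the state space models: a Gaussian linear regression
through the origin fitted by ordinary least squares, and a Poisson
log-linear regression fitted by Newton's method on its concave
log-likelihood.  Both report log-likelihood and AICc on the same scale as
the state space fits so the model classes can be compared directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .estimation import aicc as _aicc


def _aicc_or_nan(loglik: float, npar: int, T: int) -> float:
    """AICc, or NaN when the penalty is undefined (T <= npar + 1)."""
    if T <= npar + 1:
        return float("nan")
    return _aicc(loglik, npar, T)

__all__ = ["RegressionResult", "fit_gaussian_regression", "fit_poisson_regression"]

_LOG2PI = np.log(2.0 * np.pi)

#: lower cap on Poisson linear predictors / coefficients when the MLE runs
#: off to -infinity (e.g. all-zero counts during a dosage phase)
POISSON_COEFF_CAP = 30.0


@dataclass
class RegressionResult:
    """Coefficients, fit quality and error bars of one baseline regression."""

    coeffs: np.ndarray
    loglik: float
    aicc: float
    npar: int
    std_errors: np.ndarray
    residual_var: float | None = None
    flags: tuple[str, ...] = ()
    kind: str = ""
    #: log-likelihood at each Newton iterate (Poisson only); monotone
    #: non-decreasing on the concave likelihood
    newton_path: tuple[float, ...] = ()

    @property
    def degenerate(self) -> bool:
        return "degenerate" in self.flags

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "coeffs": [float(c) for c in self.coeffs],
            "std_errors": [float(s) for s in self.std_errors],
            "residual_var": self.residual_var,
            "loglik": float(self.loglik),
            "aicc": float(self.aicc),
            "npar": self.npar,
            "flags": list(self.flags),
        }


def _design(y: np.ndarray, u: np.ndarray, intercept: bool):
    y = np.asarray(y, dtype=float).ravel()
    u = np.asarray(u, dtype=float)
    if u.ndim == 1:
        u = u[:, None]
    if u.shape[0] != len(y):
        raise ValueError("y and u must have the same length")
    X = np.column_stack([np.ones(len(y)), u]) if intercept else u
    return y, X


def fit_gaussian_regression(
    y: np.ndarray, u: np.ndarray, *, intercept: bool = False
) -> RegressionResult:
    """Gaussian regression of counts on dosages, no intercept by default.

    Coefficients by OLS through the origin; the residual variance uses the
    maximum-likelihood divisor ``T`` so that the log-likelihood reduces to
    ``-(T/2)(log Sigma_n + log 2pi + 1)`` for scalar data.
    """
    y, X = _design(y, u, intercept)
    T, p = X.shape
    if T < p:
        raise ValueError(f"need at least {p} observations, got {T}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design (collinear dosage columns)")
    coeffs, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coeffs
    sigma_n = float(resid @ resid) / T
    flags: tuple[str, ...] = ()
    if sigma_n <= 1e-12 * (float(y @ y) / T + 1e-300):
        # perfect fit: the Gaussian likelihood is unbounded
        return RegressionResult(
            coeffs=coeffs,
            loglik=np.inf,
            aicc=-np.inf,
            npar=p,
            std_errors=np.zeros(p),
            residual_var=0.0,
            flags=("degenerate",),
            kind="gaussian",
        )
    loglik = -0.5 * T * (np.log(sigma_n) + _LOG2PI + 1.0)
    cov = sigma_n * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return RegressionResult(
        coeffs=coeffs,
        loglik=float(loglik),
        aicc=_aicc_or_nan(float(loglik), p, T),
        npar=p,
        std_errors=se,
        residual_var=sigma_n,
        flags=flags,
        kind="gaussian",
    )


def poisson_loglik(y: np.ndarray, u: np.ndarray, coeffs: np.ndarray) -> float:
    """Poisson log-likelihood with log link and linear predictor ``u @ b``."""
    y = np.asarray(y, dtype=float).ravel()
    u = np.asarray(u, dtype=float)
    if u.ndim == 1:
        u = u[:, None]
    eta = u @ np.asarray(coeffs, dtype=float)
    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1)))


def fit_poisson_regression(
    y: np.ndarray,
    u: np.ndarray,
    *,
    intercept: bool = False,
    max_newton_steps: int = 100,
    tol: float = 1e-10,
) -> RegressionResult:
    """Poisson log-linear regression of counts on dosages (scalar data).

    Newton iteration on the concave log-likelihood
    ``sum_t [y_t eta_t - exp(eta_t) - log(y_t!)]`` with ``eta_t = u_t @ b``;
    error bars from the inverse Fisher information.  Coefficients running
    off to -infinity (boundary MLE) are capped and flagged.
    """
    y_arr = np.asarray(y)
    if np.any(y_arr < 0):
        raise ValueError("Poisson regression requires non-negative counts")
    if not np.allclose(y_arr, np.round(y_arr)):
        raise ValueError("Poisson regression requires integer counts")
    y, X = _design(y_arr, u, intercept)
    T, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design (collinear dosage columns)")

    b = np.zeros(p)
    flags: list[str] = []
    converged = False
    path = [poisson_loglik(y, X, b)]
    for _ in range(max_newton_steps):
        eta = np.clip(X @ b, -POISSON_COEFF_CAP, POISSON_COEFF_CAP)
        mu = np.exp(eta)
        grad = X.T @ (y - mu)
        fisher = (X * mu[:, None]).T @ X
        try:
            step = np.linalg.solve(fisher, grad)
        except np.linalg.LinAlgError:
            flags.append("singular_information")
            break
        b_new = b + step
        hit = np.abs(b_new) > POISSON_COEFF_CAP
        if np.any(hit):
            b_new = np.clip(b_new, -POISSON_COEFF_CAP, POISSON_COEFF_CAP)
            if "boundary" not in flags:
                flags.append("boundary")
        if np.max(np.abs(b_new - b)) < tol:
            b = b_new
            path.append(poisson_loglik(y, X, b))
            converged = True
            break
        b = b_new
        path.append(poisson_loglik(y, X, b))
    if not converged and "boundary" not in flags:
        flags.append("newton_not_converged")

    ll = poisson_loglik(y, X, b)
    eta = np.clip(X @ b, -POISSON_COEFF_CAP, POISSON_COEFF_CAP)
    fisher = (X * np.exp(eta)[:, None]).T @ X
    try:
        se = np.sqrt(np.diag(np.linalg.inv(fisher)))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return RegressionResult(
        coeffs=b,
        loglik=ll,
        aicc=_aicc_or_nan(ll, p, T),
        npar=p,
        std_errors=se,
        residual_var=None,
        flags=tuple(flags),
        kind="poisson",
        newton_path=tuple(path),
    )
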