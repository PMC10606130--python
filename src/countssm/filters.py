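"""State estimation: linear Kalman filter, iterated EKF, and the SVD
square-root iterated EKF.

All three filters share one contract: given assembled model matrices (and,
for the nonlinear variants, an observation function) plus the observed
count series and the control series, they return a :class:`FilterOutput`
holding per-time predicted/filtered states and covariances, innovations,
innovation variances, per-term log-likelihood contributions and, for the
iterated filters, the full inner-iteration trace at every time point.

The SVD variant never forms a covariance by subtraction: predicted and
filtered covariances are produced by singular value decompositions of
stacked pre-arrays, so positive semi-definiteness holds by construction.
That is the property that lets ensembles of randomly initialized models be
fitted without numerical breakdown of the recursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import _kernels
from .model import ModelMatrices, ObservationFunction

__all__ = [
    "SvdFactor",
    "FilterConfig",
    "FilterStatus",
    "FilterOutput",
    "NotPositiveSemidefiniteError",
    "svd_factorize",
    "linear_kalman_filter",
    "iekf_filter",
    "svd_iekf_filter",
]


class NotPositiveSemidefiniteError(ValueError):
    """Raised when a matrix that must be PSD has a clearly negative eigenvalue."""


class FilterStatus(str, Enum):
    OK = "ok"
    DIVERGED = "diverged"
    NUMERICAL_FAILURE = "numerical_failure"


_STATUS_FROM_CODE = {
    _kernels.OK: FilterStatus.OK,
    _kernels.DIVERGED: FilterStatus.DIVERGED,
    _kernels.NUMERICAL_FAILURE: FilterStatus.NUMERICAL_FAILURE,
}


@dataclass
class SvdFactor:
    """A PSD matrix held as ``M = W diag(sigma^2) W^T``.

    ``W`` is orthogonal and ``sigma`` holds the non-negative singular
    values of the symmetric factorization, sorted descending.
    """

    W: np.ndarray
    sigma: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return (self.W * self.sigma**2) @ self.W.T


def svd_factorize(M: np.ndarray, *, rtol: float = 1e-8) -> SvdFactor:
    """Factorize a symmetric PSD matrix as ``W diag(sigma^2) W^T``.

    The input is symmetrized as ``(M + M^T)/2`` first; singular values are
    the square roots of the (clipped-at-zero) eigenvalues.  An eigenvalue
    below ``-rtol * ||M||`` means the matrix is not PSD and raises
    :class:`NotPositiveSemidefiniteError`.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("svd_factorize expects a square matrix")
    Ms = 0.5 * (M + M.T)
    eigvals, eigvecs = np.linalg.eigh(Ms)
    norm = max(np.abs(eigvals).max(), 1.0e-300)
    if eigvals.min() < -rtol * norm:
        raise NotPositiveSemidefiniteError(
            f"matrix has eigenvalue {eigvals.min():.3e} < -{rtol:.0e} * ||M||"
        )
    order = np.argsort(eigvals)[::-1]
    sigma = np.sqrt(np.clip(eigvals[order], 0.0, None))
    W = eigvecs[:, order]
    return SvdFactor(W=np.ascontiguousarray(W), sigma=sigma)


@dataclass
class FilterConfig:
    """Knobs of the filter recursion.

    iter_tol
        Inner iteration stops when the norm of the relative change of the
        filtered-state iterate falls below this (default 1e-10).
    iter_max
        Hard cap on inner iterations per time point (default 100).
    state_norm_guard
        Abort the recursion (status ``diverged``) when the state norm
        exceeds this; far above any plausible state but below overflow.
    x0, P0
        Initial state (zeros) and covariance (identity) if not given.
    """

    iter_tol: float = 1e-10
    iter_max: int = 100
    state_norm_guard: float = 1e50
    x0: np.ndarray | None = None
    P0: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.iter_tol <= 0:
            raise ValueError("iter_tol must be positive")
        if self.iter_max < 1:
            raise ValueError("iter_max must be at least 1")

    def initial_state(self, m: int) -> tuple[np.ndarray, np.ndarray]:
        x0 = np.zeros(m) if self.x0 is None else np.asarray(self.x0, float)
        P0 = np.eye(m) if self.P0 is None else np.asarray(self.P0, float)
        if x0.shape != (m,) or P0.shape != (m, m):
            raise ValueError("x0/P0 dimensions do not match the model")
        return x0, P0


@dataclass
class FilterOutput:
    """Everything the forward recursion produced.

    On failure the arrays are truncated to the steps completed before
    ``failure_time``; ``status`` says why the recursion stopped.
    """

    x_pred: np.ndarray
    P_pred: np.ndarray
    x_filt: np.ndarray
    P_filt: np.ndarray
    innovations: np.ndarray
    innovation_var: np.ndarray
    loglik_terms: np.ndarray
    iter_counts: np.ndarray
    iter_traces: list[np.ndarray] = field(repr=False)
    status: FilterStatus = FilterStatus.OK
    failure_time: int | None = None

    @property
    def ok(self) -> bool:
        return self.status is FilterStatus.OK

    @property
    def T(self) -> int:
        return len(self.innovations)

    @property
    def loglik(self) -> float:
        if not self.ok:
            return -np.inf
        return float(self.loglik_terms.sum())

    @property
    def max_iter_count(self) -> int:
        return int(self.iter_counts.max()) if len(self.iter_counts) else 0

    def converged_everywhere(self, iter_max: int) -> bool:
        """True when every time point's inner iteration stopped by tolerance."""
        return self.ok and bool(np.all(self.iter_counts < iter_max))


def _prepare_series(
    mat: ModelMatrices, y: np.ndarray, u: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    y = np.ascontiguousarray(np.asarray(y, dtype=float)).ravel()
    u = np.asarray(u, dtype=float)
    if u.ndim == 1:
        u = u[:, None]
    u = np.ascontiguousarray(u)
    if len(y) < 1:
        raise ValueError("series must have at least one observation")
    if u.shape[0] != len(y):
        raise ValueError(
            f"length mismatch: {len(y)} observations vs {u.shape[0]} control rows"
        )
    if u.shape[1] != mat.control_dim:
        raise ValueError(
            f"control dimension mismatch: model expects {mat.control_dim}, "
            f"got {u.shape[1]}"
        )
    return y, u


def _assemble(out_arrays, T, status_code, fail_t, iterated: bool):
    if status_code == _kernels.OK:
        n_valid = T
        failure_time = None
    else:
        n_valid = fail_t
        failure_time = int(fail_t)
    (x_pred, P_pred, x_filt, P_filt, nu, V, ll) = (
        a[:n_valid] for a in out_arrays[:7]
    )
    if iterated:
        iters = out_arrays[7][:n_valid]
        traces_arr = out_arrays[8]
        traces = [traces_arr[t, : iters[t]].copy() for t in range(n_valid)]
    else:
        iters = np.ones(n_valid, dtype=np.int64)
        traces = [np.empty(0) for _ in range(n_valid)]
    return FilterOutput(
        x_pred=x_pred.copy(),
        P_pred=P_pred.copy(),
        x_filt=x_filt.copy(),
        P_filt=P_filt.copy(),
        innovations=nu.copy(),
        innovation_var=V.copy(),
        loglik_terms=ll.copy(),
        iter_counts=np.asarray(iters),
        iter_traces=traces,
        status=_STATUS_FROM_CODE[status_code],
        failure_time=failure_time,
    )


def linear_kalman_filter(
    mat: ModelMatrices,
    y: np.ndarray,
    u: np.ndarray,
    cfg: FilterConfig | None = None,
) -> FilterOutput:
    """Linear Kalman filter for the observation ``y = C x + eps``."""
    cfg = cfg or FilterConfig()
    y, u = _prepare_series(mat, y, u)
    x0, P0 = cfg.initial_state(mat.m)
    out = _kernels.linear_kf_kernel(
        np.ascontiguousarray(mat.A),
        np.ascontiguousarray(mat.Bu),
        np.ascontiguousarray(mat.C[0]),
        np.ascontiguousarray(mat.Q),
        mat.r,
        np.ascontiguousarray(x0),
        np.ascontiguousarray(P0),
        y,
        u,
        cfg.state_norm_guard,
    )
    return _assemble(out, len(y), out[-2], out[-1], iterated=False)


def iekf_filter(
    mat: ModelMatrices,
    f: ObservationFunction,
    y: np.ndarray,
    u: np.ndarray,
    cfg: FilterConfig | None = None,
) -> FilterOutput:
    """Iterated extended Kalman filter with dense covariance propagation.

    Covariances are updated by the textbook subtraction form, which can
    lose positive definiteness in unlucky parameter regions — that is
    reported as ``numerical_failure`` rather than raised.
    """
    cfg = cfg or FilterConfig()
    y, u = _prepare_series(mat, y, u)
    x0, P0 = cfg.initial_state(mat.m)
    out = _kernels.iekf_kernel(
        np.ascontiguousarray(mat.A),
        np.ascontiguousarray(mat.Bu),
        np.ascontiguousarray(f.c_row),
        np.ascontiguousarray(mat.Q),
        mat.r,
        np.ascontiguousarray(x0),
        np.ascontiguousarray(P0),
        y,
        u,
        f.code,
        f.k,
        cfg.iter_tol,
        cfg.iter_max,
        cfg.state_norm_guard,
    )
    return _assemble(out, len(y), out[-2], out[-1], iterated=True)


def svd_iekf_filter(
    mat: ModelMatrices,
    f: ObservationFunction,
    y: np.ndarray,
    u: np.ndarray,
    cfg: FilterConfig | None = None,
) -> FilterOutput:
    """SVD square-root iterated extended Kalman filter.

    ``Q``, ``R`` and ``P0`` are factorized once before the recursion; the
    per-step covariance updates go through pre-array SVDs, keeping every
    covariance PSD by construction.
    """
    cfg = cfg or FilterConfig()
    y, u = _prepare_series(mat, y, u)
    x0, P0 = cfg.initial_state(mat.m)
    fQ = svd_factorize(mat.Q)
    fP0 = svd_factorize(P0)
    sR = float(np.sqrt(mat.r))
    # non-zero rows of diag(sigma_Q) W_Q^T: rank(Q) of them, sorted first
    rq = int(np.sum(fQ.sigma > 1e-300))
    SQW = fQ.sigma[:rq, None] * fQ.W[:, :rq].T
    out = _kernels.svd_iekf_kernel(
        np.ascontiguousarray(mat.A),
        np.ascontiguousarray(mat.Bu),
        np.ascontiguousarray(f.c_row),
        np.ascontiguousarray(SQW),
        sR,
        np.ascontiguousarray(x0),
        np.ascontiguousarray(fP0.W),
        np.ascontiguousarray(fP0.sigma),
        y,
        u,
        f.code,
        f.k,
        cfg.iter_tol,
        cfg.iter_max,
        cfg.state_norm_guard,
    )
    return _assemble(out, len(y), out[-2], out[-1], iterated=True)


FILTERS = {
    "kf": linear_kalman_filter,
    "iekf": iekf_filter,
    "svd-iekf": svd_iekf_filter,
}


def run_filter(
    kind: str,
    mat: ModelMatrices,
    f: ObservationFunction,
    y: np.ndarray,
    u: np.ndarray,
    cfg: FilterConfig | None = None,
) -> FilterOutput:
    """Dispatch by filter name (``kf``, ``iekf`` or ``svd-iekf``)."""
    if kind == "kf":
        return linear_kalman_filter(mat, y, u, cfg)
    try:
        fn = FILTERS[kind]
    except KeyError:
        raise ValueError(f"unknown filter kind {kind!r}") from None
    return fn(mat, f, y, u, cfg)
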