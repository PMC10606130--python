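"""Maximum innovation-likelihood fitting and model selection.

Parameters are estimated by numerically maximizing the innovation
(prediction-error) log-likelihood produced by the forward filter
recursion; models of different complexity — including the non-dynamic
baselines — are compared on the corrected Akaike information criterion
(AICc).  Because the likelihood surface of an iterated nonlinear filter
has many local optima on short series, fitting is organized as an
ensemble of random restarts and the minimum-AICc member is retained.

Constrained parameters (AR coefficients, variances) are optimized in
unconstrained coordinates via smooth bijections; the observation weights
are fixed at 1.0 and the ARMA block's control gains at 0 to avoid
redundancy with the control gain matrix, so they are never part of the
free parameter vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize

from .filters import FilterConfig, FilterOutput, FilterStatus, run_filter
from .model import (
    ArmaComponent,
    DrugComponent,
    ObservationFunction,
    StateSpaceModel,
)

__all__ = [
    "innovation_loglik",
    "aicc",
    "ParameterTransform",
    "FitResult",
    "EnsembleResult",
    "fit_model",
    "fit_ensemble",
    "hessian_std_errors",
    "numerical_hessian",
    "errors_from_hessian",
]

_LOG2PI = math.log(2.0 * math.pi)
DRUG_AR_CAP = 0.99

#: default lower bound on the fitted observation noise variance.  Counts are
#: rounded model outputs, so the effective observation error includes a
#: quantization term of variance 1/12; without this floor the Gaussian
#: innovation likelihood is unbounded (r -> 0 while long zero-count
#: stretches are predicted exactly) and the optimizer chases a degenerate
#: spike instead of the data-describing optimum.
OBS_NOISE_FLOOR = 1.0 / 12.0


def innovation_loglik(filter_output: FilterOutput, n: int = 1) -> float:
    """Gaussian prediction-error decomposition of the log-likelihood.

    ``logL = -1/2 sum_t (log|V_t| + nu_t' V_t^{-1} nu_t) - nT/2 log 2pi``
    using the final-iteration innovations; the initial state's contribution
    is ignored.  Scalar-data path: ``V_t`` and ``nu_t`` are scalars.
    """
    if not filter_output.ok:
        raise ValueError(
            f"filter did not complete (status={filter_output.status.value})"
        )
    nu = filter_output.innovations
    V = filter_output.innovation_var
    if np.any(V <= 0):
        raise ValueError("non-positive innovation variance")
    T = len(nu)
    return float(-0.5 * np.sum(np.log(V) + nu**2 / V) - 0.5 * n * T * _LOG2PI)


def aicc(loglik: float, npar: int, T: int) -> float:
    """Corrected AIC: ``-2 logL + 2 Npar T / (T - Npar - 1)``."""
    if T <= npar + 1:
        raise ValueError(
            f"AICc undefined: need T > npar + 1 (T={T}, npar={npar})"
        )
    return -2.0 * loglik + 2.0 * npar * T / (T - npar - 1)


# --------------------------------------------------------------------------
# parameter packing between reporting scale and unconstrained coordinates


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


class ParameterTransform:
    """Bijection between the free parameters of a model and R^npar.

    Reporting scale (the order of ``names``): per drug block ``(ar_coeff,
    control_gain)``, per ARMA block ``(a1, a2, b1, sigma)``, then the
    observation noise variance ``r`` and optionally the observation shape
    parameter ``k``.  Unconstrained coordinates use a scaled logistic for
    the drug AR coefficient, a partial-autocorrelation (tanh) map for the
    AR(2) stationarity triangle, and logs for the variances.
    """

    def __init__(
        self,
        template: StateSpaceModel,
        estimate_k: bool = False,
        obs_noise_floor: float = OBS_NOISE_FLOOR,
    ):
        self.template = template
        self.estimate_k = estimate_k
        self.obs_noise_floor = float(obs_noise_floor)
        names: list[str] = []
        drug_i = 0
        for comp in template.components:
            if isinstance(comp, DrugComponent):
                names += [f"drug{drug_i + 1}_ar", f"drug{drug_i + 1}_gain"]
                drug_i += 1
            else:
                names += ["arma_a1", "arma_a2", "arma_b1", "arma_sigma"]
        names.append("r")
        if estimate_k:
            names.append("k")
        self.names = names

    @property
    def npar(self) -> int:
        return len(self.names)

    # -- natural (reporting-scale) vector -----------------------------
    def natural_from_model(self, model: StateSpaceModel) -> np.ndarray:
        vals: list[float] = []
        for comp in model.components:
            if isinstance(comp, DrugComponent):
                vals += [comp.ar_coeff, comp.control_gain]
            else:
                vals += [
                    comp.ar1_coeff,
                    comp.ar2_coeff,
                    comp.ma_coeff,
                    comp.noise_sd,
                ]
        vals.append(model.obs_noise_var)
        if self.estimate_k:
            vals.append(model.obs_k)
        return np.array(vals, dtype=float)

    def model_from_natural(self, theta: np.ndarray) -> StateSpaceModel:
        theta = np.asarray(theta, dtype=float)
        comps: list = []
        i = 0
        for comp in self.template.components:
            if isinstance(comp, DrugComponent):
                comps.append(
                    DrugComponent(
                        ar_coeff=float(theta[i]),
                        control_gain=float(theta[i + 1]),
                        control_index=comp.control_index,
                    )
                )
                i += 2
            else:
                comps.append(
                    ArmaComponent(
                        ar1_coeff=float(theta[i]),
                        ar2_coeff=float(theta[i + 1]),
                        ma_coeff=float(theta[i + 2]),
                        noise_sd=float(theta[i + 3]),
                    )
                )
                i += 4
        obs_noise_var = float(theta[i])
        i += 1
        k = float(theta[i]) if self.estimate_k else self.template.obs_k
        return StateSpaceModel(
            components=comps,
            obs_noise_var=obs_noise_var,
            obs_kind=self.template.obs_kind,
            obs_k=k,
            control_dim=self.template.control_dim,
        )

    # -- unconstrained coordinates -------------------------------------
    def pack(self, theta_nat: np.ndarray) -> np.ndarray:
        """Reporting scale -> unconstrained coordinates."""
        theta_nat = np.asarray(theta_nat, dtype=float)
        out: list[float] = []
        i = 0
        for comp in self.template.components:
            if isinstance(comp, DrugComponent):
                out.append(_logit(theta_nat[i] / DRUG_AR_CAP))
                out.append(theta_nat[i + 1])
                i += 2
            else:
                a1, a2 = theta_nat[i], theta_nat[i + 1]
                # partial autocorrelations of the AR(2) part
                r2 = a2
                r1 = a1 / (1.0 - a2)
                out += [math.atanh(r1), math.atanh(r2)]
                out.append(theta_nat[i + 2])
                out.append(math.log(theta_nat[i + 3]))
                i += 4
        # free coordinate is log of the variance in excess of the floor
        out.append(math.log(max(theta_nat[i] - self.obs_noise_floor, 1e-12)))
        i += 1
        if self.estimate_k:
            out.append(math.log(theta_nat[i]))
        return np.array(out, dtype=float)

    def unpack(self, phi: np.ndarray) -> np.ndarray:
        """Unconstrained coordinates -> reporting scale."""
        phi = np.asarray(phi, dtype=float)
        out: list[float] = []
        i = 0
        for comp in self.template.components:
            if isinstance(comp, DrugComponent):
                out.append(DRUG_AR_CAP * _expit(phi[i]))
                out.append(phi[i + 1])
                i += 2
            else:
                r1 = math.tanh(phi[i])
                r2 = math.tanh(phi[i + 1])
                out += [r1 * (1.0 - r2), r2]
                out.append(phi[i + 2])
                out.append(math.exp(phi[i + 3]))
                i += 4
        out.append(self.obs_noise_floor + math.exp(phi[i]))
        i += 1
        if self.estimate_k:
            out.append(math.exp(phi[i]))
        return np.array(out, dtype=float)

    def random_natural(self, rng: np.random.Generator) -> np.ndarray:
        """Random initial parameters for one restart of the ensemble."""
        vals: list[float] = []
        for comp in self.template.components:
            if isinstance(comp, DrugComponent):
                vals.append(rng.uniform(0.1, 0.9))
                vals.append(rng.uniform(-1.0, 1.0))
            else:
                # uniform over the AR(2) stationarity triangle shrunk by 0.9
                while True:
                    a1 = rng.uniform(-1.8, 1.8)
                    a2 = rng.uniform(-0.9, 0.9)
                    if abs(a1) < 0.9 - a2:
                        break
                vals += [a1, a2]
                vals.append(rng.uniform(-0.5, 0.5))
                vals.append(math.exp(rng.uniform(math.log(0.05), 0.0)))
        vals.append(
            self.obs_noise_floor + math.exp(rng.uniform(math.log(0.05), 0.0))
        )
        if self.estimate_k:
            vals.append(1.0)
        return np.array(vals, dtype=float)


# --------------------------------------------------------------------------
# single-model fit


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    params: dict[str, float]
    loglik: float
    aicc: float
    npar: int
    converged: bool
    filter_output: FilterOutput | None
    model: StateSpaceModel | None
    seed: int | None = None
    std_errors: dict[str, float] | None = None
    std_errors_flag: str | None = None
    n_failed_evals: int = 0
    n_indefinite_evals: int = 0
    n_diverged_evals: int = 0
    n_nonconverged_evals: int = 0
    init_filter_status: str | None = None
    init_converged_everywhere: bool | None = None
    optimizer_message: str = ""
    # context needed to recompute the likelihood (for Hessian errors)
    _context: dict = field(default_factory=dict, repr=False)

    @property
    def gains(self) -> dict[str, float]:
        return {k: v for k, v in self.params.items() if k.endswith("_gain")}

    @property
    def filter_ok(self) -> bool:
        return self.filter_output is not None and self.filter_output.ok

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "loglik": self.loglik,
            "aicc": self.aicc,
            "npar": self.npar,
            "converged": self.converged,
            "seed": self.seed,
            "std_errors": self.std_errors,
            "std_errors_flag": self.std_errors_flag,
            "n_failed_evals": self.n_failed_evals,
        }


def _make_objective(
    transform: ParameterTransform,
    y: np.ndarray,
    u: np.ndarray,
    filter_kind: str,
    cfg: FilterConfig,
    counters: dict,
) -> Callable[[np.ndarray], float]:
    template = transform.template

    def negloglik(phi: np.ndarray) -> float:
        try:
            theta = transform.unpack(phi)
        except (OverflowError, ValueError):
            counters["failed"] += 1
            return np.inf
        try:
            model = transform.model_from_natural(theta)
            mat = model.matrices()
            f = ObservationFunction(
                kind=model.obs_kind, c_row=mat.C[0], k=model.obs_k
            )
            fo = run_filter(filter_kind, mat, f, y, u, cfg)
        except (ValueError, FloatingPointError):
            counters["failed"] += 1
            return np.inf
        if not fo.ok:
            counters["failed"] += 1
            if fo.status is FilterStatus.NUMERICAL_FAILURE:
                counters["indefinite"] += 1
            else:
                counters["diverged"] += 1
            return np.inf
        if not fo.converged_everywhere(cfg.iter_max):
            counters["nonconverged"] += 1
        return -fo.loglik

    return negloglik


def fit_model(
    model: StateSpaceModel,
    y: np.ndarray,
    u: np.ndarray,
    init: np.ndarray | None = None,
    *,
    filter_kind: str = "svd-iekf",
    cfg: FilterConfig | None = None,
    optimizer: str = "hybrid",
    estimate_k: bool = False,
    obs_noise_floor: float = OBS_NOISE_FLOOR,
    seed: int | None = None,
    simplex_maxiter: int = 150,
    polish_maxiter: int = 15,
) -> FitResult:
    """Fit one model by maximizing the innovation log-likelihood.

    ``init`` is a reporting-scale parameter vector (see
    :class:`ParameterTransform`); if omitted, the template model's own
    parameter values start the search.  A filter failure during the search
    is penalized with ``+inf`` rather than raised, so the optimizer can
    back away from pathological parameter regions.

    ``optimizer`` is ``"nelder-mead"``, ``"bfgs"`` or ``"hybrid"``
    (simplex exploration followed by a quasi-Newton polish).
    """
    cfg = cfg or FilterConfig()
    transform = ParameterTransform(
        model, estimate_k=estimate_k, obs_noise_floor=obs_noise_floor
    )
    y = np.asarray(y, dtype=float).ravel()
    T = len(y)
    if T <= transform.npar + 1:
        raise ValueError(
            f"series too short: T={T} must exceed npar+1={transform.npar + 1}"
        )
    theta0 = (
        transform.natural_from_model(model)
        if init is None
        else np.asarray(init, dtype=float)
    )
    phi0 = transform.pack(theta0)

    counters = {"failed": 0, "indefinite": 0, "diverged": 0, "nonconverged": 0}
    objective = _make_objective(transform, y, u, filter_kind, cfg, counters)

    # probe the randomly initialized model itself: filters that misbehave
    # tend to show it already at the starting parameters
    init_model = transform.model_from_natural(theta0)
    init_mat = init_model.matrices()
    init_f = ObservationFunction(
        kind=init_model.obs_kind, c_row=init_mat.C[0], k=init_model.obs_k
    )
    init_fo = run_filter(filter_kind, init_mat, init_f, y, u, cfg)
    init_status = init_fo.status.value
    init_conv = init_fo.converged_everywhere(cfg.iter_max)

    messages = []
    phi = phi0
    if optimizer in ("hybrid", "nelder-mead"):
        res = optimize.minimize(
            objective,
            phi,
            method="Nelder-Mead",
            options={
                "maxiter": simplex_maxiter,
                "fatol": 1e-8,
                "xatol": 1e-6,
            },
        )
        phi = res.x
        messages.append(f"nelder-mead: {res.message}")
    if optimizer in ("hybrid", "bfgs"):
        with np.errstate(all="ignore"):
            res = optimize.minimize(
                objective,
                phi,
                method="BFGS",
                options={"maxiter": polish_maxiter, "gtol": 1e-5},
            )
        if np.isfinite(res.fun) and res.fun <= objective(phi):
            phi = res.x
        messages.append(f"bfgs: {res.message}")
    if optimizer not in ("hybrid", "nelder-mead", "bfgs"):
        raise ValueError(f"unknown optimizer {optimizer!r}")

    theta = transform.unpack(phi)
    fitted = transform.model_from_natural(theta)
    mat = fitted.matrices()
    f = ObservationFunction(kind=fitted.obs_kind, c_row=mat.C[0], k=fitted.obs_k)
    fo = run_filter(filter_kind, mat, f, y, u, cfg)
    if fo.ok:
        ll = innovation_loglik(fo)
        crit = aicc(ll, transform.npar, T)
        converged = True
    else:
        ll = -np.inf
        crit = np.inf
        converged = False

    return FitResult(
        params=dict(zip(transform.names, theta)),
        loglik=ll,
        aicc=crit,
        npar=transform.npar,
        converged=converged,
        filter_output=fo,
        model=fitted,
        seed=seed,
        n_failed_evals=counters["failed"],
        n_indefinite_evals=counters["indefinite"],
        n_diverged_evals=counters["diverged"],
        n_nonconverged_evals=counters["nonconverged"],
        init_filter_status=init_status,
        init_converged_everywhere=init_conv,
        optimizer_message="; ".join(messages),
        _context={
            "y": y,
            "u": np.asarray(u, dtype=float),
            "filter_kind": filter_kind,
            "cfg": cfg,
            "transform": transform,
        },
    )


# --------------------------------------------------------------------------
# ensembles


@dataclass
class EnsembleResult:
    """A random-restart ensemble of fits and its minimum-AICc member."""

    members: list[FitResult]
    best_index: int
    n_indefinite: int
    n_diverged: int
    n_poor_convergence: int

    @property
    def best(self) -> FitResult:
        return self.members[self.best_index]

    @property
    def failure_count(self) -> int:
        return self.n_indefinite + self.n_diverged + self.n_poor_convergence

    def gain_vs_aicc(self) -> pd.DataFrame:
        """Long table of (member, drug, gain, aicc, status) for scatter plots."""
        rows = []
        for i, mres in enumerate(self.members):
            status = _member_status(mres)
            for drug, gain in mres.gains.items():
                rows.append(
                    {
                        "member": i,
                        "drug": drug,
                        "gain": gain,
                        "aicc": mres.aicc,
                        "status": status,
                    }
                )
        return pd.DataFrame(rows)


def _member_status(mres: FitResult) -> str:
    """Classify one restart by the worst behavior it exhibited.

    ``numerical_failure``: covariance indefiniteness / non-positive
    innovation variance at any likelihood evaluation.  ``diverged``: the
    recursion at the optimum blew past the state-norm guard.
    ``poor_convergence``: the inner iteration hit its cap at some time
    point, either for the randomly initialized model or at the optimum.
    """
    if (
        mres.n_indefinite_evals > 0
        or mres.filter_output is not None
        and mres.filter_output.status is FilterStatus.NUMERICAL_FAILURE
    ):
        return "numerical_failure"
    if not mres.filter_ok:
        return "diverged"
    cfg = mres._context.get("cfg") or FilterConfig()
    if not mres.filter_output.converged_everywhere(cfg.iter_max):
        return "poor_convergence"
    if mres.init_filter_status == "ok" and mres.init_converged_everywhere is False:
        return "poor_convergence"
    return "ok"


def fit_ensemble(
    model: StateSpaceModel,
    y: np.ndarray,
    u: np.ndarray,
    size: int,
    seed: int,
    *,
    filter_kind: str = "svd-iekf",
    cfg: FilterConfig | None = None,
    optimizer: str = "hybrid",
    estimate_k: bool = False,
    obs_noise_floor: float = OBS_NOISE_FLOOR,
    **fit_kwargs,
) -> EnsembleResult:
    """Fit ``size`` randomly initialized models and keep the best by AICc.

    Every member draws its initial parameters from one seeded generator, so
    identical (seed, size) invocations are bit-identical.  Members whose
    optimization encountered covariance indefiniteness, whose filter
    diverged at the optimum, or whose inner iteration failed to converge at
    some time point are counted but never raised.
    """
    if size < 1:
        raise ValueError("ensemble size must be at least 1")
    rng = np.random.default_rng(seed)
    transform = ParameterTransform(
        model, estimate_k=estimate_k, obs_noise_floor=obs_noise_floor
    )
    members: list[FitResult] = []
    for j in range(size):
        init = transform.random_natural(rng)
        mres = fit_model(
            model,
            y,
            u,
            init=init,
            filter_kind=filter_kind,
            cfg=cfg,
            optimizer=optimizer,
            estimate_k=estimate_k,
            obs_noise_floor=obs_noise_floor,
            seed=seed,
            **fit_kwargs,
        )
        members.append(mres)

    statuses = [_member_status(m) for m in members]
    n_indef = sum(s == "numerical_failure" for s in statuses)
    n_div = sum(s == "diverged" for s in statuses)
    n_poor = sum(s == "poor_convergence" for s in statuses)

    candidates = [i for i, m in enumerate(members) if m.converged]
    if not candidates:
        raise RuntimeError("no converged model in the ensemble")
    best_index = min(candidates, key=lambda i: members[i].aicc)
    return EnsembleResult(
        members=members,
        best_index=best_index,
        n_indefinite=n_indef,
        n_diverged=n_div,
        n_poor_convergence=n_poor,
    )


# --------------------------------------------------------------------------
# error bars from the local curvature


def numerical_hessian(
    f: Callable[[np.ndarray], float], theta: np.ndarray, step: float = 1e-4
) -> np.ndarray:
    """Central-difference Hessian of ``f`` at ``theta`` (step per coordinate)."""
    theta = np.asarray(theta, dtype=float)
    p = len(theta)
    H = np.empty((p, p))
    f0 = f(theta)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = step
        H[i, i] = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / step**2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(theta + ei + ej)
                - f(theta + ei - ej)
                - f(theta - ei + ej)
                + f(theta - ei - ej)
            ) / (4.0 * step**2)
    return H


def errors_from_hessian(H: np.ndarray) -> tuple[np.ndarray, str]:
    """Standard errors from a Hessian of the negative log-likelihood.

    Returns ``(errors, flag)``; flag is ``"ok"``, ``"not_positive_definite"``
    (errors computed from \\|diagonal\\| of the pseudo-inverse, unreliable) or
    ``"singular"`` (errors unavailable, NaN).
    """
    H = np.asarray(H, dtype=float)
    p = H.shape[0]
    if not np.all(np.isfinite(H)):
        return np.full(p, np.nan), "singular"
    eigvals = np.linalg.eigvalsh(0.5 * (H + H.T))
    scale = max(np.abs(eigvals).max(), 1e-300)
    if np.abs(eigvals).min() < 1e-12 * scale:
        return np.full(p, np.nan), "singular"
    cov = np.linalg.inv(H)
    diag = np.diag(cov)
    if eigvals.min() <= 0 or np.any(diag <= 0):
        return np.sqrt(np.abs(diag)), "not_positive_definite"
    return np.sqrt(diag), "ok"


def hessian_std_errors(result: FitResult, step: float = 1e-4) -> FitResult:
    """Attach Hessian-based standard errors to a fitted model (in place).

    The Hessian of the negative log-likelihood is taken by central
    differences in the reporting scale of each parameter.  With an inner
    filter iteration at every time point the likelihood surface can be
    locally rough, so these errors are known to be optimistic at times;
    a non-positive-definite Hessian is surfaced through
    ``std_errors_flag`` instead of being silently inverted.
    """
    ctx = result._context
    if not ctx:
        raise ValueError("FitResult carries no refit context")
    transform: ParameterTransform = ctx["transform"]
    y, u = ctx["y"], ctx["u"]
    filter_kind, cfg = ctx["filter_kind"], ctx["cfg"]

    def neg_ll_natural(theta: np.ndarray) -> float:
        try:
            model = transform.model_from_natural(theta)
            mat = model.matrices()
            f = ObservationFunction(
                kind=model.obs_kind, c_row=mat.C[0], k=model.obs_k
            )
            fo = run_filter(filter_kind, mat, f, y, u, cfg)
        except ValueError:
            return np.inf
        return -fo.loglik if fo.ok else np.inf

    theta = np.array([result.params[name] for name in transform.names])
    H = numerical_hessian(neg_ll_natural, theta, step=step)
    errors, flag = errors_from_hessian(H)
    result.std_errors = dict(zip(transform.names, errors))
    result.std_errors_flag = flag
    return result
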