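"""Model family for count time series: independent-component linear state
space dynamics with a nonlinear, non-negativity-enforcing observation.

The latent state is partitioned into independent blocks, one per component:

* ``drug`` blocks — deterministic AR(1) responses to an external control
  input (e.g. a daily drug dosage).  The block contributes no dynamical
  noise; its single state carries the accumulated, delayed effect of the
  dosage, scaled by a control gain whose sign is the scientific verdict
  (negative gain = event-reducing).
* ``arma`` blocks — a stochastic ARMA(2,1) process capturing temporal
  correlation in the counts unrelated to the controls.

The observed count is a noisy, rounded image of a scalar linear read-out
``z = C x`` pushed through an observation function that keeps the model
output non-negative (exponential, affinely distorted hyperbolic, or
softplus).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "DrugComponent",
    "ArmaComponent",
    "Component",
    "ModelMatrices",
    "ObservationFunction",
    "StateSpaceModel",
    "build_model_matrices",
    "observation_eval",
    "observation_jacobian",
]

#: Upper bound for the AR(1) coefficient of a drug-response block.  The
#: block models pharmacological carry-over, so the coefficient is kept
#: non-negative and strictly below 1 (a negative value would oscillate on
#: a daily grid, which carry-over dynamics do not do).
DRUG_AR_MAX = 0.99

_OBS_KINDS = ("identity", "exponential", "adh", "softplus")
# integer codes shared with the jitted filter kernels
OBS_CODE = {kind: i for i, kind in enumerate(_OBS_KINDS)}


@dataclass(frozen=True)
class DrugComponent:
    """Deterministic AR(1) response of the latent state to one control input.

    Parameters
    ----------
    ar_coeff
        Carry-over coefficient in ``[0, 0.99)``; 0 means the effect follows
        the dosage instantaneously, values near 1 mean long delays.
    control_gain
        Coupling from dosage to state, in state units per dosage unit.
    control_index
        Which column of the control series this block responds to.
    """

    ar_coeff: float
    control_gain: float
    control_index: int = 0

    kind = "drug_ar1"
    state_dim = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar_coeff < DRUG_AR_MAX):
            raise ValueError(
                f"drug AR(1) coefficient must lie in [0, {DRUG_AR_MAX}), "
                f"got {self.ar_coeff}"
            )
        if self.control_index < 0:
            raise ValueError("control_index must be non-negative")


@dataclass(frozen=True)
class ArmaComponent:
    """Stochastic ARMA(2,1) block in innovations state space form.

    The two-state realization ``A = [[a1, 1], [a2, 0]]`` with noise gain
    ``g = [1, b1]^T`` makes the first state exactly the ARMA(2,1) process

        x_t = a1 x_{t-1} + a2 x_{t-2} + eta_t + b1 eta_{t-1}

    so the fixed unit observation weight picks the process itself.
    """

    ar1_coeff: float
    ar2_coeff: float
    ma_coeff: float
    noise_sd: float

    kind = "arma21"
    state_dim = 2

    def __post_init__(self) -> None:
        a1, a2 = self.ar1_coeff, self.ar2_coeff
        # stationarity triangle of an AR(2) polynomial
        if not (-1.0 < a2 < 1.0 and a2 + a1 < 1.0 and a2 - a1 < 1.0):
            raise ValueError(
                f"ARMA(2,1) AR part (a1={a1}, a2={a2}) is not stationary"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


Component = DrugComponent | ArmaComponent


@dataclass
class ModelMatrices:
    """Assembled state space matrices with block bookkeeping.

    ``A`` and ``Q`` are block-diagonal with identical partitions; ``C`` has
    weight 1.0 on the first state of each block and 0 elsewhere, and the
    control gain rows of the ARMA block are zero, so all free parameters
    live in the blocks and in ``R``.
    """

    A: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    C: np.ndarray
    Bu: np.ndarray
    block_index: list[tuple[Component, slice]]

    @property
    def m(self) -> int:
        return self.A.shape[0]

    @property
    def control_dim(self) -> int:
        return self.Bu.shape[1]

    @property
    def r(self) -> float:
        """Scalar observation noise variance (scalar-data path)."""
        return float(self.R[0, 0])


def build_model_matrices(
    components: Sequence[Component],
    obs_noise_var: float,
    control_dim: int,
) -> ModelMatrices:
    """Assemble block-diagonal ``A``, ``Q``, ``Bu`` and the fixed ``C`` row.

    Each drug block contributes a 1x1 transition ``[a]``, a zero noise
    block, and a single control gain entry; each ARMA block contributes the
    2-state innovations-form transition and the rank-one noise covariance
    ``sigma^2 g g^T`` with ``g = [1, b1]^T``.
    """
    if len(components) == 0:
        raise ValueError("at least one component is required")
    if obs_noise_var <= 0:
        raise ValueError("observation noise variance must be positive")

    m = sum(c.state_dim for c in components)
    A = np.zeros((m, m))
    Q = np.zeros((m, m))
    Bu = np.zeros((m, control_dim))
    C = np.zeros((1, m))
    blocks: list[tuple[Component, slice]] = []

    pos = 0
    for comp in components:
        sl = slice(pos, pos + comp.state_dim)
        if isinstance(comp, DrugComponent):
            if comp.control_index >= control_dim:
                raise ValueError(
                    f"control_index {comp.control_index} out of range for "
                    f"control_dim {control_dim}"
                )
            A[pos, pos] = comp.ar_coeff
            Bu[pos, comp.control_index] = comp.control_gain
        elif isinstance(comp, ArmaComponent):
            A[sl, sl] = [[comp.ar1_coeff, 1.0], [comp.ar2_coeff, 0.0]]
            g = np.array([1.0, comp.ma_coeff])
            Q[sl, sl] = comp.noise_sd**2 * np.outer(g, g)
        else:  # pragma: no cover - future component kinds
            raise TypeError(f"unknown component type {type(comp)!r}")
        C[0, pos] = 1.0
        blocks.append((comp, sl))
        pos += comp.state_dim

    R = np.array([[float(obs_noise_var)]])
    return ModelMatrices(A=A, Q=Q, R=R, C=C, Bu=Bu, block_index=blocks)


@dataclass(frozen=True)
class ObservationFunction:
    """Scalar observation function ``y = f(C x)`` and its Jacobian.

    Kinds
    -----
    identity
        ``f(z) = z`` — recovers the linear Gaussian model.
    exponential
        ``f(z) = exp(z)`` — strictly positive but divergent for large
        positive arguments; known to break plain EKF-type filters.
    adh
        The affinely distorted hyperbolic function
        ``f(z) = z/2 + sqrt(z^2/4 + k)``: behaves like ``exp`` for very
        negative ``z``, approaches the line ``z`` for large positive ``z``.
    softplus
        ``f(z) = k log(1 + exp(z/k))`` — same qualitative shape as adh.
    """

    kind: str
    c_row: np.ndarray
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _OBS_KINDS:
            raise ValueError(f"unknown observation kind {self.kind!r}")
        if self.kind in ("adh", "softplus") and self.k <= 0:
            raise ValueError(f"{self.kind} requires k > 0, got {self.k}")
        object.__setattr__(
            self, "c_row", np.atleast_1d(np.asarray(self.c_row, dtype=float))
        )

    @property
    def code(self) -> int:
        return OBS_CODE[self.kind]

    def __call__(self, x: np.ndarray) -> float:
        return observation_eval(self, x)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        return observation_jacobian(self, x)


def _eval_scalar(kind: str, z: float, k: float) -> float:
    if kind == "identity":
        return z
    if kind == "exponential":
        with np.errstate(over="ignore"):
            return float(np.exp(z))  # +inf on overflow; guard is the caller's
    if kind == "adh":
        return z / 2.0 + np.sqrt(z * z / 4.0 + k)
    # softplus, numerically stable in both tails
    return k * np.logaddexp(0.0, z / k)


def _deriv_scalar(kind: str, z: float, k: float) -> float:
    if kind == "identity":
        return 1.0
    if kind == "exponential":
        with np.errstate(over="ignore"):
            return float(np.exp(z))
    if kind == "adh":
        return 0.5 + z / (4.0 * np.sqrt(z * z / 4.0 + k))
    from scipy.special import expit

    return float(expit(z / k))


def observation_eval(f: ObservationFunction, x: np.ndarray) -> float:
    """Evaluate ``f(C x)`` for a state vector ``x``."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    z = float(f.c_row @ x)
    return float(_eval_scalar(f.kind, z, f.k))


def observation_jacobian(f: ObservationFunction, x: np.ndarray) -> np.ndarray:
    """Row vector ``H = df/dx`` evaluated at ``x`` (chain rule through C)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    z = float(f.c_row @ x)
    return _deriv_scalar(f.kind, z, f.k) * f.c_row


@dataclass
class StateSpaceModel:
    """A full model specification: components, observation, noise.

    This is the object the fitting routines consume; ``matrices()`` and
    ``observation()`` produce the concrete numeric pieces.
    """

    components: list[Component]
    obs_noise_var: float = 0.1
    obs_kind: str = "adh"
    obs_k: float = 1.0
    control_dim: int | None = None

    def __post_init__(self) -> None:
        if self.control_dim is None:
            idx = [
                c.control_index
                for c in self.components
                if isinstance(c, DrugComponent)
            ]
            self.control_dim = (max(idx) + 1) if idx else 1

    @property
    def m(self) -> int:
        return sum(c.state_dim for c in self.components)

    @property
    def drug_components(self) -> list[DrugComponent]:
        return [c for c in self.components if isinstance(c, DrugComponent)]

    @property
    def arma_components(self) -> list[ArmaComponent]:
        return [c for c in self.components if isinstance(c, ArmaComponent)]

    def matrices(self) -> ModelMatrices:
        return build_model_matrices(
            self.components, self.obs_noise_var, self.control_dim
        )

    def observation(self) -> ObservationFunction:
        return ObservationFunction(
            kind=self.obs_kind, c_row=self.matrices().C[0], k=self.obs_k
        )

    def with_updates(self, **kwargs) -> "StateSpaceModel":
        return replace(self, **kwargs)

    # -- configuration round trip -------------------------------------
    def to_dict(self) -> dict:
        comps = []
        for c in self.components:
            if isinstance(c, DrugComponent):
                comps.append(
                    {
                        "kind": "drug_ar1",
                        "ar_coeff": float(c.ar_coeff),
                        "control_gain": float(c.control_gain),
                        "control_index": int(c.control_index),
                    }
                )
            else:
                comps.append(
                    {
                        "kind": "arma21",
                        "ar1_coeff": float(c.ar1_coeff),
                        "ar2_coeff": float(c.ar2_coeff),
                        "ma_coeff": float(c.ma_coeff),
                        "noise_sd": float(c.noise_sd),
                    }
                )
        return {
            "components": comps,
            "obs_noise_var": float(self.obs_noise_var),
            "observation": {"kind": self.obs_kind, "k": float(self.obs_k)},
            "control_dim": int(self.control_dim),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StateSpaceModel":
        comps: list[Component] = []
        for c in d["components"]:
            kind = c.get("kind")
            if kind == "drug_ar1":
                comps.append(
                    DrugComponent(
                        ar_coeff=c["ar_coeff"],
                        control_gain=c["control_gain"],
                        control_index=c.get("control_index", 0),
                    )
                )
            elif kind == "arma21":
                comps.append(
                    ArmaComponent(
                        ar1_coeff=c["ar1_coeff"],
                        ar2_coeff=c["ar2_coeff"],
                        ma_coeff=c["ma_coeff"],
                        noise_sd=c["noise_sd"],
                    )
                )
            else:
                raise ValueError(f"unknown component kind {kind!r}")
        obs = d.get("observation", {})
        return cls(
            components=comps,
            obs_noise_var=d.get("obs_noise_var", 0.1),
            obs_kind=obs.get("kind", "adh"),
            obs_k=obs.get("k", 1.0),
            control_dim=d.get("control_dim"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StateSpaceModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
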