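"""Synthetic daily event-count generator for the validation study.

The generator emulates a simulated "patient" given three drugs (AED1-3)
with piecewise-constant daily dosages over 500 days.  Each drug drives a
deterministic AR(1) latent response scaled by a control gain (AED1 and
AED3 reduce the event rate, AED2 increases it); an additive stochastic
ARMA(2,1) component models fluctuations unrelated to the drugs.  The
latent sum passes through the affinely distorted hyperbolic observation
function, receives Gaussian observation noise, and is rounded to a
non-negative integer — the simulated daily count.

Default dynamics and noise levels are recorded constants, calibrated once
so that the default scenario's counts span the realistic range 0-6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ArmaComponent, DrugComponent, ObservationFunction, StateSpaceModel

__all__ = [
    "Segment",
    "SimConfig",
    "SimOutput",
    "make_dosage_profiles",
    "simulate_counts",
    "DEFAULT_SEGMENTS",
    "DEFAULT_TRUE_GAINS",
]

#: (start_day, end_day, dose); days are 1-based and inclusive
Segment = tuple[int, int, float]

#: control gains of the simulated drugs ("correct values"): AED1 and AED3
#: reduce the daily count, AED2 increases it
DEFAULT_TRUE_GAINS = (-0.40, 0.95, -0.70)

#: staggered on/off/titration dosage schedule over 500 days, covering
#: start-up, overlap and withdrawal phases for each drug.  Each drug's dose
#: changes several times while the predicted count is in the responsive
#: range of the observation function, so that carry-over (AR coefficient)
#: and control gain are separately identifiable rather than only their
#: steady-state ratio.
DEFAULT_SEGMENTS: tuple[tuple[Segment, ...], ...] = (
    ((61, 180, 1.0), (181, 300, 2.0), (301, 420, 0.5)),                  # AED1
    ((1, 120, 1.6), (121, 240, 1.25), (241, 360, 0.75), (361, 480, 1.25)),   # AED2
    ((141, 260, 0.5), (261, 380, 1.0), (381, 500, 0.5)),                 # AED3
)


@dataclass
class SimConfig:
    """Study conditions of the simulated scenario."""

    T: int = 500
    segments: tuple[tuple[Segment, ...], ...] = DEFAULT_SEGMENTS
    true_gains: tuple[float, ...] = DEFAULT_TRUE_GAINS
    drug_ar: tuple[float, ...] = (0.7, 0.7, 0.7)
    arma: tuple[float, float, float, float] = (1.2, -0.35, 0.2, 0.08)
    obs_kind: str = "adh"
    obs_k: float = 1.0
    obs_noise_var: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be at least 1")
        if len(self.true_gains) != len(self.segments) or len(self.drug_ar) != len(
            self.segments
        ):
            raise ValueError("segments, true_gains and drug_ar must align")

    @property
    def n_drugs(self) -> int:
        return len(self.true_gains)

    def true_model(self) -> StateSpaceModel:
        """The generating model, also the template for fitting."""
        comps: list = [
            DrugComponent(ar_coeff=a, control_gain=g, control_index=i)
            for i, (a, g) in enumerate(zip(self.drug_ar, self.true_gains))
        ]
        a1, a2, b1, sigma = self.arma
        comps.append(
            ArmaComponent(ar1_coeff=a1, ar2_coeff=a2, ma_coeff=b1, noise_sd=sigma)
        )
        return StateSpaceModel(
            components=comps,
            obs_noise_var=self.obs_noise_var,
            obs_kind=self.obs_kind,
            obs_k=self.obs_k,
            control_dim=self.n_drugs,
        )


@dataclass
class SimOutput:
    """One realization of the simulated scenario."""

    counts: np.ndarray
    latent_states: np.ndarray
    pre_round: np.ndarray
    dosages: np.ndarray
    config: SimConfig

    def to_frame(self) -> pd.DataFrame:
        cols = {"day": np.arange(1, len(self.counts) + 1), "count": self.counts}
        for j in range(self.dosages.shape[1]):
            cols[f"aed{j + 1}"] = self.dosages[:, j]
        return pd.DataFrame(cols)


def make_dosage_profiles(
    T: int, segments: tuple[tuple[Segment, ...], ...]
) -> np.ndarray:
    """Piecewise-constant dosage series, one column per drug.

    Days not covered by any segment get dose 0; overlapping segments for
    the same drug are rejected.
    """
    u = np.zeros((T, len(segments)))
    for j, segs in enumerate(segments):
        covered = np.zeros(T, dtype=bool)
        for start, end, dose in segs:
            if not (1 <= start <= end <= T):
                raise ValueError(
                    f"drug {j + 1}: segment ({start}, {end}) outside [1, {T}]"
                )
            if dose < 0:
                raise ValueError(f"drug {j + 1}: negative dose {dose}")
            sl = slice(start - 1, end)
            if covered[sl].any():
                raise ValueError(f"drug {j + 1}: overlapping segments")
            covered[sl] = True
            u[sl, j] = dose
    return u


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def simulate_counts(cfg: SimConfig) -> SimOutput:
    """Generate one count series under the configured scenario.

    States evolve by the linear dynamics with control input (drug blocks
    deterministic, ARMA block driven by Gaussian noise); the observation is
    ``f(C x) + eps`` with ``eps ~ N(0, r)``, rounded half-away-from-zero
    and clamped at zero.  A fixed seed gives bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    model = cfg.true_model()
    mat = model.matrices()
    f = ObservationFunction(kind=cfg.obs_kind, c_row=mat.C[0], k=cfg.obs_k)
    u = make_dosage_profiles(cfg.T, cfg.segments)

    m = mat.m
    a1, a2, b1, sigma = cfg.arma
    g = np.array([1.0, b1])
    arma_sl = mat.block_index[-1][1]  # ARMA block is appended last

    # all random draws happen regardless of noise levels, so disabling a
    # noise source (sigma=0 or r=0) does not shift the remaining stream
    eta = rng.standard_normal(cfg.T)
    eps = rng.standard_normal(cfg.T)

    x = np.zeros(m)
    states = np.empty((cfg.T, m))
    pre = np.empty(cfg.T)
    for t in range(cfg.T):
        x = mat.A @ x + mat.Bu @ u[t]
        x[arma_sl] += sigma * g * eta[t]
        states[t] = x
        pre[t] = f(x) + np.sqrt(cfg.obs_noise_var) * eps[t]

    counts = np.maximum(_round_half_away(pre), 0.0).astype(int)
    return SimOutput(
        counts=counts,
        latent_states=states,
        pre_round=pre,
        dosages=u,
        config=cfg,
    )
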