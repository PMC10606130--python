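"""Innovation whiteness diagnostics.

A well-specified model should leave innovations (one-step prediction
errors) that are white noise; residual autocorrelation signals structure
the model failed to capture.  The check compares the sample ACF of the
innovations against the usual ``±1/sqrt(T)`` band and contrasts it with
the ACF of the raw counts, which is strongly autocorrelated by
construction (dosage phases persist for months).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf as _sm_acf

from .filters import FilterOutput

__all__ = ["AcfResult", "acf", "WhitenessReport", "whiteness_summary"]


@dataclass
class AcfResult:
    """Sample autocorrelation function with a whiteness reference band."""

    lags: np.ndarray
    values: np.ndarray
    band: float

    @property
    def n_outside(self) -> int:
        """Lags 1..L whose |ACF| exceeds the band."""
        return int(np.sum(np.abs(self.values[1:]) > self.band))

    @property
    def frac_inside(self) -> float:
        return 1.0 - self.n_outside / (len(self.values) - 1)


def acf(series: np.ndarray, max_lag: int) -> AcfResult:
    """Mean-removed sample ACF normalized by the lag-0 autocovariance.

    The reference band is ``1/sqrt(T)``, the asymptotic one-standard-
    deviation band of the sample ACF of white noise.
    """
    series = np.asarray(series, dtype=float).ravel()
    T = len(series)
    if max_lag < 1:
        raise ValueError("max_lag must be at least 1")
    if T <= max_lag:
        raise ValueError(f"series length {T} must exceed max_lag {max_lag}")
    if np.var(series) == 0:
        raise ValueError("ACF undefined for a constant series")
    values = _sm_acf(series, nlags=max_lag, adjusted=False, fft=False)
    return AcfResult(
        lags=np.arange(max_lag + 1), values=values, band=1.0 / np.sqrt(T)
    )


@dataclass
class WhitenessReport:
    """Side-by-side ACF of innovations and raw data, with a pass verdict."""

    innovations: AcfResult
    raw: AcfResult
    passed: bool
    frac_inside_required: float
    band_sigmas: float

    @property
    def frac_inside(self) -> float:
        """Fraction of innovation-ACF lags inside the evaluation band."""
        wide = self.band_sigmas * self.innovations.band
        return float(np.mean(np.abs(self.innovations.values[1:]) <= wide))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag": self.innovations.lags,
                "acf_innovations": self.innovations.values,
                "acf_raw": self.raw.values,
                "band": self.innovations.band,
            }
        )


def whiteness_summary(
    filter_output: FilterOutput,
    raw_series: np.ndarray,
    max_lag: int = 30,
    frac_inside_required: float = 0.9,
    band_sigmas: float = 2.0,
) -> WhitenessReport:
    """Whiteness verdict for a fitted model's innovations.

    Passes when at least ``frac_inside_required`` of the innovation-ACF
    lags 1..max_lag lie inside ``band_sigmas`` standard deviations of the
    white-noise sampling band (``band_sigmas / sqrt(T)``) while the raw
    series' ACF violates the same band at one or more lags — i.e. the
    model actually removed autocorrelation that was present.  The default
    two-standard-deviation band makes the 90% bar meaningful: a truly
    white series leaves about 68% of sample-ACF lags inside a one-sd band
    but about 95% inside two.
    """
    if not filter_output.ok:
        raise ValueError("whiteness summary requires a completed filter run")
    innov_acf = acf(filter_output.innovations, max_lag)
    raw_acf = acf(raw_series, max_lag)
    wide = band_sigmas * innov_acf.band
    frac_inside = float(np.mean(np.abs(innov_acf.values[1:]) <= wide))
    raw_outside = int(np.sum(np.abs(raw_acf.values[1:]) > wide))
    passed = frac_inside >= frac_inside_required and raw_outside >= 1
    return WhitenessReport(
        innovations=innov_acf,
        raw=raw_acf,
        passed=passed,
        frac_inside_required=frac_inside_required,
        band_sigmas=band_sigmas,
    )
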