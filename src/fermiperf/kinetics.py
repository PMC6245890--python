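"""Tracer-kinetic building blocks.

Two ingredients drive first-pass perfusion quantification:

* a **gamma-variate bolus model** for the arterial input function (AIF),
  the contrast concentration in the left-ventricular blood pool, and
* the **Fermi impulse-response model** ``h(t) = F / (1 + exp(k (t - tau0)))``
  whose convolution with the AIF predicts the myocardial tissue curve.
  Myocardial blood flow (MBF) is read out as ``h(0)``.

The forward model here is shared by the phantom generator (synthesis) and
the deconvolution fitter (inference), so round-trip consistency is exact
by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import SampledCurve
from .exceptions import InvalidParameterError

__all__ = [
    "AifParams",
    "FermiParams",
    "make_aif",
    "fermi_impulse_response",
    "make_tissue_curve",
    "tissue_curve_values",
]


@dataclass(frozen=True)
class AifParams:
    """Gamma-variate bolus parameters for the arterial input function.

    The main pass is the normalized gamma-variate

    ``C_a(t) = baseline + amplitude * ((t - onset)/(alpha*beta))**alpha
               * exp(alpha - (t - onset)/beta)``  for ``t > onset``

    (and ``baseline`` before onset), which peaks at exactly
    ``amplitude + baseline`` at ``t = onset + alpha*beta``.  An optional
    recirculation pass adds a delayed, scaled copy of the main bolus.

    Parameters
    ----------
    amplitude : float
        Peak enhancement above baseline, signal units.
    onset : float
        Bolus arrival time t_a, seconds.
    alpha : float
        Dimensionless shape parameter, > 0.
    beta : float
        Time-scale parameter, seconds, > 0.
    recirculation_fraction : float
        Amplitude fraction of the recirculation pass, in [0, 1).
    recirculation_delay : float
        Delay of the recirculation pass relative to the main bolus, s.
    baseline : float
        Pre-contrast signal level.
    """

    amplitude: float = 1.0
    onset: float = 8.0
    alpha: float = 3.0
    beta: float = 2.0
    recirculation_fraction: float = 0.0
    recirculation_delay: float = 25.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise InvalidParameterError("alpha and beta must be positive")
        if not (0.0 <= self.recirculation_fraction < 1.0):
            raise InvalidParameterError("recirculation_fraction must be in [0, 1)")
        for f in (self.amplitude, self.onset, self.alpha, self.beta,
                  self.recirculation_fraction, self.recirculation_delay,
                  self.baseline):
            if not math.isfinite(f):
                raise InvalidParameterError("AIF parameters must be finite")

    def scaled(self, factor: float) -> "AifParams":
        """Bolus diluted/concentrated by `factor` (baseline unchanged)."""
        return AifParams(self.amplitude * factor, self.onset, self.alpha,
                         self.beta, self.recirculation_fraction,
                         self.recirculation_delay, self.baseline)


def _gamma_variate(times: np.ndarray, amplitude: float, onset: float,
                   alpha: float, beta: float) -> np.ndarray:
    t = np.asarray(times, dtype=float) - onset
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / (alpha * beta)
    out[pos] = amplitude * np.power(x, alpha) * np.exp(alpha - t[pos] / beta)
    return out


def make_aif(params: AifParams, times: np.ndarray) -> SampledCurve:
    """Evaluate the gamma-variate AIF on a time grid.

    ``times`` must be strictly increasing.  Returns ``baseline`` for all
    ``t <= onset``; the recirculation pass, if any, is
    ``recirculation_fraction`` times the main bolus delayed by
    ``recirculation_delay``.
    """
    times = np.asarray(times, dtype=float)
    vals = _gamma_variate(times, params.amplitude, params.onset,
                          params.alpha, params.beta)
    if params.recirculation_fraction > 0:
        vals = vals + params.recirculation_fraction * _gamma_variate(
            times, params.amplitude, params.onset + params.recirculation_delay,
            params.alpha, params.beta)
    return SampledCurve(times, vals + params.baseline)


@dataclass(frozen=True)
class FermiParams:
    """Fermi impulse-response parameters.

    ``h(t) = F / (1 + exp(k * (t - tau0)))`` for t >= 0 and 0 before;
    ``F`` is the flow amplitude (arbitrary flow units per second of the
    time axis), ``k`` the decay rate (1/s), ``tau0`` the shoulder width
    (s) and ``td`` a pure arrival delay (s) applied to the input.  The
    flow read-out is ``h(0) = F / (1 + exp(-k * tau0))``.
    """

    F: float
    k: float = 0.25
    tau0: float = 4.0
    td: float = 0.0

    def __post_init__(self) -> None:
        if self.F < 0 or self.k < 0 or self.tau0 < 0 or self.td < 0:
            raise InvalidParameterError("Fermi parameters must be non-negative")
        if not all(math.isfinite(v) for v in (self.F, self.k, self.tau0, self.td)):
            raise InvalidParameterError("Fermi parameters must be finite")

    @property
    def mbf(self) -> float:
        """Myocardial blood flow h(0) = F / (1 + exp(-k * tau0))."""
        return self.F / (1.0 + math.exp(-self.k * self.tau0))

    @classmethod
    def from_mbf(cls, mbf: float, k: float = 0.25, tau0: float = 4.0,
                 td: float = 0.0) -> "FermiParams":
        """Construct parameters whose h(0) equals a target flow."""
        return cls(mbf * (1.0 + math.exp(-k * tau0)), k, tau0, td)


def fermi_impulse_response(params: FermiParams, times: np.ndarray) -> np.ndarray:
    """h(t) on a time grid; zero for t < 0, non-increasing for t >= 0."""
    t = np.asarray(times, dtype=float)
    out = np.zeros_like(t)
    nn = t >= 0
    out[nn] = params.F / (1.0 + np.exp(np.clip(params.k * (t[nn] - params.tau0),
                                               -700, 700)))
    return out


def tissue_curve_values(aif_values: np.ndarray, times: np.ndarray,
                        params: FermiParams) -> np.ndarray:
    """Discrete forward model: tissue = dt * conv(AIF delayed by td, h).

    The delay is applied by linear interpolation of the AIF, so the model
    is smooth in ``td`` (important for the fitter).  Assumes a uniform
    time grid; the AIF is extended with its first value before the series
    start (zero for baseline-free input).
    """
    times = np.asarray(times, dtype=float)
    aif_values = np.asarray(aif_values, dtype=float)
    dt = times[1] - times[0]
    shifted = np.interp(times - params.td, times, aif_values,
                        left=aif_values[0])
    h = fermi_impulse_response(params, times - times[0])
    full = np.convolve(shifted, h)[: times.size]
    return dt * full


def make_tissue_curve(aif: SampledCurve, params: FermiParams) -> SampledCurve:
    """Convolve a (baseline-free) AIF with the Fermi impulse response.

    Requires uniform sampling; a baseline-free input yields a
    baseline-free output.  Flow linearity holds exactly: doubling ``F``
    doubles the output pointwise.
    """
    aif.require_uniform()
    vals = tissue_curve_values(aif.values, aif.times, params)
    return SampledCurve(aif.times, vals)
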