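"""Boltzmann and single-exponential fits for hERG channel gating data.

Voltage dependence of activation (and steady-state inactivation) follows
a Boltzmann sigmoid

    I/Imax = 1 / (1 + exp[(V1/2 - V) / k])

with half-activation voltage V1/2 (mV) and slope factor k (mV).  The
slope factor is constrained positive; whether the curve rises or falls
with voltage is carried by an explicit orientation flag, so activation
(rising) and steady-state inactivation (falling) data are both fitted
with positive k, matching how the parameters are conventionally quoted.

Time courses (envelope-of-tails activation, inactivation decay) are
fitted by a single exponential with free amplitude and offset; the time
constant τ (ms) is the quantity of interest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GatingDataset",
    "BoltzmannFit",
    "ExponentialFit",
    "normalize_tail_currents",
    "percent_inhibition",
    "fit_boltzmann",
    "fit_single_exponential",
]

GATING_KINDS = (
    "boltzmann_activation",
    "boltzmann_inactivation",
    "exponential_rise",
    "exponential_decay",
)


@dataclass(frozen=True)
class GatingDataset:
    """x is voltage (mV) for Boltzmann kinds or duration (ms) for
    exponential kinds; y is normalized current (dimensionless)."""

    kind: str
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in GATING_KINDS:
            raise ValueError(f"unknown gating kind {self.kind!r}; expected one of {GATING_KINDS}")
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.shape != x.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values")


@dataclass(frozen=True)
class BoltzmannFit:
    v_half: float  # mV
    k_slope: float  # mV, always positive
    orientation: str  # 'rising' or 'falling'
    residual_sum_squares: float

    def __post_init__(self) -> None:
        if self.k_slope <= 0:
            raise ValueError("k_slope must be positive; direction lives in `orientation`")
        if self.orientation not in ("rising", "falling"):
            raise ValueError(f"orientation must be 'rising' or 'falling', got {self.orientation!r}")


@dataclass(frozen=True)
class ExponentialFit:
    tau: float  # ms
    amplitude: float
    offset: float
    residual_sum_squares: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def normalize_tail_currents(raw_peaks: Iterable[float]) -> np.ndarray:
    """Divide peak amplitudes by the maximum absolute peak.

    The largest-magnitude peak maps to ±1; signs are preserved so inward
    and outward components stay distinguishable.
    """
    peaks = np.asarray(list(raw_peaks), dtype=float)
    if peaks.size == 0 or not np.any(peaks > 0):
        raise ValueError("need at least one strictly positive peak to normalize")
    return peaks / np.max(np.abs(peaks))


def percent_inhibition(control_peak: float, drug_peak: float) -> float:
    """Blockade as percent reduction of the tail-current peak."""
    if control_peak <= 0:
        raise ValueError(f"control peak must be positive, got {control_peak}")
    return 100.0 * (1.0 - drug_peak / control_peak)


def boltzmann(v: np.ndarray, v_half: float, k: float, orientation: str = "rising") -> np.ndarray:
    """Evaluate the Boltzmann sigmoid with positive slope factor k."""
    rising = 1.0 / (1.0 + np.exp((v_half - v) / k))
    return rising if orientation == "rising" else 1.0 - rising


def fit_boltzmann(data: GatingDataset) -> BoltzmannFit:
    """Least-squares Boltzmann fit, selecting the better orientation.

    Both the rising and the falling parameterization are fitted with
    k > 0 and the lower-residual one is returned, so the caller never
    has to guess the sign convention of its dataset.
    """
    x, y = data.x, data.y
    if x.size < 4:
        raise ValueError("Boltzmann fit requires at least 4 points")
    if np.ptp(y) < 0.05:
        raise ValueError("data are flat (y range < 0.05): Boltzmann parameters unidentifiable")

    # centered voltage coordinates make the fit shift-equivariant to
    # machine precision
    center = x.mean()
    xc = x - center
    span = max(np.ptp(x) / 10.0, 1e-3)
    best: tuple[float, np.ndarray, str] | None = None
    for orientation in ("rising", "falling"):
        target = y if orientation == "rising" else 1.0 - y
        mid = float(xc[np.argmin(np.abs(target - 0.5))])

        def residuals(theta, _o=orientation):
            return boltzmann(xc, theta[0], np.exp(theta[1]), _o) - y

        sol = least_squares(
            residuals, [mid, np.log(span)], xtol=1e-15, ftol=1e-15, gtol=1e-15
        )
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x, orientation)
    rss, popt, orientation = best
    return BoltzmannFit(
        v_half=float(popt[0] + center),
        k_slope=float(np.exp(popt[1])),
        orientation=orientation,
        residual_sum_squares=rss,
    )


def fit_single_exponential(data: GatingDataset, shape: str) -> ExponentialFit:
    """Fit A·(1−exp(−t/τ))+c (rise) or A·exp(−t/τ)+c (decay).

    Amplitude and offset are free because raw tail amplitudes need not
    be normalized; τ is the compared quantity.
    """
    if shape not in ("rise", "decay"):
        raise ValueError(f"shape must be 'rise' or 'decay', got {shape!r}")
    t, y = data.x, data.y
    if t.size < 4:
        raise ValueError("exponential fit requires at least 4 points")
    if np.any(t < 0):
        raise ValueError("durations must be non-negative")

    tau0 = max(np.ptp(t) / 3.0, 1e-6)
    amp0 = y[-1] - y[0] if shape == "rise" else y[0] - y[-1]
    amp0 = amp0 if amp0 != 0 else max(np.ptp(y), 1e-6)
    off0 = y[0] if shape == "rise" else y[-1]

    def residuals(theta):
        tau, amp, off = np.exp(theta[0]), theta[1], theta[2]
        if shape == "rise":
            return amp * (1.0 - np.exp(-t / tau)) + off - y
        return amp * np.exp(-t / tau) + off - y

    sol = least_squares(
        residuals, [np.log(tau0), amp0, off0], xtol=1e-15, ftol=1e-15, gtol=1e-15
    )
    converged = bool(sol.success)
    popt = sol.x
    rss = float(np.sum(sol.fun**2))
    return ExponentialFit(
        tau=float(np.exp(popt[0])),
        amplitude=float(popt[1]),
        offset=float(popt[2]),
        residual_sum_squares=rss,
        converged=converged,
    )
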