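"""Chou median-effect analysis of dose-effect data.

The median-effect equation relates dose D to the fraction of channels
affected, ``fa``::

    fa / fu = (D / Dm)^m,      fu = 1 - fa

where ``Dm`` is the median-effect dose (the dose producing fa = 0.5) and
``m`` describes the sigmoidicity of the curve (the analogue of the Hill
coefficient).  Taking base-10 logarithms linearizes the relation,

    log10(fa/fu) = m * log10(D) - m * log10(Dm),

so ordinary least squares on the transformed points yields the slope
``m``, the x-intercept ``log10(Dm)`` and the linear correlation
coefficient ``r`` -- the three parameters reported for every drug and
mixture.  The dose producing an arbitrary effect level follows by
inversion, ``Dx = Dm * (fa/(1-fa))^(1/m)``, which is the quantity the
combination-index calculation consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dose_response import DoseResponseTable

__all__ = [
    "MedianEffectFit",
    "ExcludedPoint",
    "linearize",
    "fit_median_effect",
    "dose_for_effect",
    "effect_at_dose",
]


@dataclass(frozen=True)
class ExcludedPoint:
    """A (dose, fa) pair left out of the linearized fit, with the reason."""

    dose: float
    fa: float
    reason: str


@dataclass(frozen=True)
class MedianEffectFit:
    """Result of the linearized median-effect fit.

    ``dm`` is stored as ``10**(-intercept/m)`` so the triple
    (m, intercept, dm) is always internally consistent.
    """

    m: float
    dm: float
    r: float
    intercept: float
    points_used: int
    excluded_points: tuple[ExcludedPoint, ...] = ()
    flags: tuple[str, ...] = ()
    drug_id: str = ""

    def __post_init__(self) -> None:
        if self.points_used < 2:
            raise ValueError("median-effect fit requires >= 2 points")
        if not -1.0 <= self.r <= 1.0 + 1e-15:
            raise ValueError(f"correlation coefficient out of range: {self.r}")
        if self.dm <= 0:
            raise ValueError(f"Dm must be positive, got {self.dm}")


def linearize(table: DoseResponseTable) -> tuple[np.ndarray, list[ExcludedPoint]]:
    """Transform a dose-effect table to median-effect plot coordinates.

    Each point with 0 < fa < 1 maps to ``(log10 D, log10(fa/(1-fa)))``.
    Boundary points (fa exactly 0 or 1) have undefined log-odds and are
    excluded, each with a recorded reason.

    Returns
    -------
    points : (n, 2) array of (x, y) coordinates
    excluded : list of :class:`ExcludedPoint`
    """
    xs, ys, excluded = [], [], []
    for dose, fa in zip(table.doses, table.fa):
        if fa <= 0.0:
            excluded.append(ExcludedPoint(float(dose), float(fa), "fa <= 0: log-odds undefined"))
        elif fa >= 1.0:
            excluded.append(ExcludedPoint(float(dose), float(fa), "fa >= 1: log-odds undefined"))
        else:
            xs.append(np.log10(dose))
            ys.append(np.log10(fa / (1.0 - fa)))
    if len(xs) < 2:
        raise ValueError(
            f"only {len(xs)} usable points with 0 < fa < 1; "
            "at least 2 are required for the median-effect fit"
        )
    return np.column_stack([xs, ys]), excluded


def fit_median_effect(table: DoseResponseTable) -> MedianEffectFit:
    """Fit the median-effect equation by OLS on the linearized points.

    m is the slope, Dm the anti-log of the x-intercept and r the Pearson
    correlation coefficient of the linearized points.  A non-positive
    slope (effect decreasing with dose) is reported but flagged
    ``non-monotone`` rather than raised, so screening runs can continue.
    """
    points, excluded = linearize(table)
    x, y = points[:, 0], points[:, 1]
    if np.ptp(x) == 0.0:
        raise ValueError("all usable doses identical: slope is undefined")
    res = stats.linregress(x, y)
    m = float(res.slope)
    intercept = float(res.intercept)
    flags: tuple[str, ...] = ()
    if m <= 0:
        flags = ("non-monotone",)
        # Dm undefined for m <= 0; fall back on the geometric-mean dose so
        # the record is still representable, carrying the flag.
        dm = float(10.0 ** np.mean(x))
    else:
        dm = float(10.0 ** (-intercept / m))
    return MedianEffectFit(
        m=m,
        dm=dm,
        r=float(res.rvalue),
        intercept=intercept,
        points_used=len(x),
        excluded_points=tuple(excluded),
        flags=flags,
        drug_id=table.drug_id,
    )


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dose Dx producing effect level fa: ``Dx = Dm * (fa/(1-fa))^(1/m)``."""
    if fa <= 0.0:
        raise ValueError(f"fa must exceed 0 (got {fa}): no finite dose gives zero effect")
    if fa >= 1.0:
        raise ValueError(f"fa must be below 1 (got {fa}): complete effect needs infinite dose")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def effect_at_dose(fit: MedianEffectFit, dose: float) -> float:
    """Forward median-effect curve: ``fa = 1 / (1 + (Dm/D)^m)``."""
    if dose <= 0.0:
        raise ValueError(f"dose must be positive, got {dose}")
    return 1.0 / (1.0 + (fit.dm / dose) ** fit.m)
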