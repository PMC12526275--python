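"""Hill concentration-response fitting for hERG tail-current blockade.

Fractional blockade B as a function of drug concentration [D] follows

    B(%) = 100 / (1 + (IC50 / [D])^n)

with half-maximal inhibitory concentration IC50 and Hill coefficient n.
The objective is evaluated on the percent-blockade scale, unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["DoseResponseTable", "HillFit", "fit_hill", "predict_hill"]


@dataclass(frozen=True)
class DoseResponseTable:
    """One drug's doses (μM) and mean fractional inhibition per dose.

    ``replicates`` optionally carries per-cell fa values, one row per
    dose level, so either per-cell or mean-level fitting conventions can
    be exercised downstream.
    """

    drug_id: str
    doses: np.ndarray
    fa: np.ndarray
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        fa = np.asarray(self.fa, dtype=float)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "fa", fa)
        if doses.ndim != 1 or fa.shape != doses.shape:
            raise ValueError("doses and fa must be 1-D arrays of equal length")
        bad = doses[doses <= 0]
        if bad.size:
            raise ValueError(f"non-positive dose not allowed: {bad[0]} μM")
        if np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be strictly increasing with no duplicates")
        if np.any((fa < 0) | (fa > 1)):
            raise ValueError("every fa must lie in [0, 1]")
        if self.replicates is not None:
            reps = np.asarray(self.replicates, dtype=float)
            object.__setattr__(self, "replicates", reps)
            if reps.shape[0] != doses.size:
                raise ValueError("replicates must have one row per dose level")

    @classmethod
    def from_unsorted(
        cls,
        drug_id: str,
        doses: np.ndarray,
        fa: np.ndarray,
        replicates: np.ndarray | None = None,
    ) -> "DoseResponseTable":
        """Build a table from rows in arbitrary order (sorts by dose)."""
        doses = np.asarray(doses, dtype=float)
        fa = np.asarray(fa, dtype=float)
        order = np.argsort(doses)
        reps = None
        if replicates is not None:
            reps = np.asarray(replicates, dtype=float)[order]
        return cls(drug_id, doses[order], fa[order], reps)


@dataclass(frozen=True)
class HillFit:
    ic50: float
    n_hill: float
    residual_sum_squares: float  # percent^2
    converged: bool
    extrapolated: bool = False  # IC50 beyond the top tested dose
    drug_id: str = ""

    def __post_init__(self) -> None:
        if self.converged and (self.ic50 <= 0 or self.n_hill <= 0):
            raise ValueError("converged Hill fit must have positive IC50 and n")


def fit_hill(table: DoseResponseTable) -> HillFit:
    """Least-squares Hill fit on the percent-blockade scale.

    Minimizes Σ (100·fa_obs − 100/[1+(IC50/D)^n])² over IC50 > 0, n > 0
    in log-parameter space.  IC50 is bounded to [min dose / 1e3,
    max dose · 1e3] and n to [0.05, 10]; an IC50 above the highest tested
    dose is reported but flagged as extrapolated.
    """
    doses, fa = table.doses, table.fa
    interior = (fa > 0) & (fa < 1)
    if doses.size < 3 or interior.sum() < 2:
        raise ValueError(
            "Hill fit requires >= 3 dose levels with 0 < fa < 1 at two or more of them"
        )
    y = 100.0 * fa

    # work in log-dose coordinates centered on the geometric-mean dose:
    # rescaling every dose by c then leaves the optimization problem
    # numerically identical, so the fit is scale-equivariant to
    # machine precision
    log_d = np.log(doses)
    center = log_d.mean()
    z = log_d - center

    # start IC50 at the dose whose fa is nearest half-effect
    r0 = float(z[interior][np.argmin(np.abs(fa[interior] - 0.5))])
    lo = np.array([z.min() - np.log(1e3), np.log(0.05)])
    hi = np.array([z.max() + np.log(1e3), np.log(10.0)])
    theta0 = np.clip([r0, 0.0], lo, hi)

    def residuals(theta: np.ndarray) -> np.ndarray:
        r, n = theta[0], np.exp(theta[1])
        return 100.0 / (1.0 + np.exp(n * (r - z))) - y

    def jacobian(theta: np.ndarray) -> np.ndarray:
        r, n = theta[0], np.exp(theta[1])
        u = np.exp(n * (r - z))
        g = -100.0 * u / (1.0 + u) ** 2
        return np.column_stack([g * n, g * (r - z) * n])

    sol = least_squares(
        residuals, theta0, jac=jacobian, bounds=(lo, hi),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    theta = sol.x
    # Gauss-Newton polish to a machine-precision stationary point (the
    # bounded solver stops with gradients around 1e-6, which leaves the
    # parameters short of the exact scale-equivariance the fit promises);
    # kept only while it stays inside the bounds
    for _ in range(8):
        J, res = jacobian(theta), residuals(theta)
        try:
            step = np.linalg.solve(J.T @ J, -J.T @ res)
        except np.linalg.LinAlgError:
            break
        candidate = theta + step
        if not (np.all(candidate >= lo) and np.all(candidate <= hi)):
            break
        if np.sum(residuals(candidate) ** 2) > np.sum(res**2) * (1 + 1e-12):
            break
        theta = candidate
        if np.max(np.abs(step)) < 1e-14:
            break
    ic50 = np.exp(theta[0] + center)
    n = np.exp(theta[1])
    rss = float(np.sum(residuals(theta) ** 2))
    return HillFit(
        ic50=float(ic50),
        n_hill=float(n),
        residual_sum_squares=rss,
        converged=bool(sol.success),
        extrapolated=bool(ic50 > doses.max()),
        drug_id=table.drug_id,
    )


def predict_hill(fit: HillFit, dose: float) -> float:
    """Fractional blockade predicted at ``dose``: 1/[1+(IC50/D)^n]."""
    if dose <= 0:
        raise ValueError(f"dose must be positive, got {dose}")
    return 1.0 / (1.0 + (fit.ic50 / dose) ** fit.n_hill)
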