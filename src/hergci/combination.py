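"""Combination-index analysis for fixed-ratio drug mixtures.

For a mixture of two or three blockers applied at a common effect level
fa, the combination index is

    CI = Σ_i  D_i / Dx_i(fa)

where D_i is the dose of component i actually present in the mixture
and Dx_i(fa) the dose of component i that, alone, would produce fa
(from its single-drug median-effect fit).  CI = 1 is Loewe additivity;
values below 0.90 indicate synergism and above 1.10 antagonism.

Two complementary evaluations are provided:

* at *observed* points — each measured mixture level contributes its
  own fa, and CI is computed from that fa and the component doses;
* at *effect levels* (ED50, ED75, ...) — the mixture is itself fitted
  as a single agent on its total dose, the total dose producing each
  target fa is read off that fit, and split between components by the
  design weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .median_effect import MedianEffectFit, dose_for_effect, fit_median_effect
from .dose_response import DoseResponseTable

__all__ = [
    "ComboDataset",
    "CIPoint",
    "CILevel",
    "CIResult",
    "EDLevelCI",
    "combination_index_at_point",
    "fit_combo_as_single",
    "ci_table",
    "ci_at_effect_levels",
    "classify_interaction",
    "fa_ci_curve",
    "SYNERGY_THRESHOLDS",
]

#: (lower, upper) CI bounds of the additive band; the band is closed on
#: both sides (CI = 0.90 and CI = 1.10 are classified additive).
SYNERGY_THRESHOLDS = (0.90, 1.10)

_RATIO_TOL = 1e-9


@dataclass(frozen=True)
class ComboDataset:
    """Fixed-ratio combination design.

    ``doses`` has one row per mixture level and one column per
    component; every row must realize the same dose proportions
    (``weights``), which is what makes the mixture fittable as a single
    agent on its total dose.
    """

    component_ids: tuple[str, ...]
    weights: np.ndarray
    doses: np.ndarray  # (n_levels, n_components), μM
    fa: np.ndarray  # (n_levels,), combined fraction affected
    design_label: str = ""

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        doses = np.asarray(self.doses, dtype=float)
        fa = np.asarray(self.fa, dtype=float)
        object.__setattr__(self, "component_ids", tuple(self.component_ids))
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "fa", fa)
        k = len(self.component_ids)
        if weights.shape != (k,):
            raise ValueError("one weight per component required")
        if np.any(weights <= 0) or abs(weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be positive and sum to 1")
        if doses.ndim != 2 or doses.shape[1] != k:
            raise ValueError("doses must be (n_levels, n_components)")
        if fa.shape != (doses.shape[0],):
            raise ValueError("one combined fa per level required")
        if np.any(doses <= 0):
            raise ValueError("all component doses must be positive")
        if np.any((fa < 0) | (fa > 1)):
            raise ValueError("combined fa must lie in [0, 1]")
        ratios = doses / doses.sum(axis=1, keepdims=True)
        off = np.abs(ratios - weights).max(axis=1)
        if np.any(off > _RATIO_TOL):
            lvl = int(np.argmax(off))
            raise ValueError(
                f"level {lvl} violates the fixed ratio: doses {doses[lvl].tolist()} "
                f"do not realize weights {weights.tolist()}"
            )

    @property
    def total_doses(self) -> np.ndarray:
        return self.doses.sum(axis=1)

    @property
    def n_levels(self) -> int:
        return self.doses.shape[0]


@dataclass(frozen=True)
class CIPoint:
    """CI at one (doses, fa) point with its per-component dose ratios."""

    ci: float
    terms: tuple[float, ...]  # D_i / Dx_i per component
    fa: float

    def __post_init__(self) -> None:
        if abs(self.ci - sum(self.terms)) > 1e-12 * max(1.0, abs(self.ci)):
            raise ValueError("CI must equal the sum of its per-component terms")


@dataclass(frozen=True)
class CILevel:
    total_dose: float
    fa: float
    ci: float | None
    terms: tuple[float, ...]
    interaction: str  # class label, or the reason CI is undefined


@dataclass(frozen=True)
class CIResult:
    component_ids: tuple[str, ...]
    per_level: tuple[CILevel, ...]


@dataclass(frozen=True)
class EDLevelCI:
    fa_levels: tuple[float, ...]
    ci_values: tuple[float, ...]
    total_doses: tuple[float, ...]
    combo_fit: MedianEffectFit

    def __post_init__(self) -> None:
        if len(self.fa_levels) != len(self.ci_values):
            raise ValueError("fa_levels and ci_values must have the same length")
        fl = np.asarray(self.fa_levels)
        if np.any((fl <= 0) | (fl >= 1)) or np.any(np.diff(fl) <= 0):
            raise ValueError("fa_levels must be strictly increasing within (0, 1)")


def combination_index_at_point(
    singles: Sequence[MedianEffectFit],
    doses: Sequence[float],
    fa: float,
) -> CIPoint:
    """CI = Σ D_i / Dx_i at a single observed point.

    ``singles`` are the single-drug median-effect fits, ``doses`` the
    component doses present in the mixture, and ``fa`` the effect level
    at which the comparison is made (normally the observed combined fa).
    """
    if len(singles) != len(doses):
        raise ValueError(f"{len(singles)} fits but {len(doses)} doses")
    if len(singles) not in (2, 3):
        raise ValueError("combination index is defined here for 2 or 3 components")
    if not 0.0 < fa < 1.0:
        raise ValueError(f"fa must lie strictly inside (0, 1), got {fa}")
    if any(d <= 0 for d in doses):
        raise ValueError("component doses must be positive")
    terms = tuple(float(d) / dose_for_effect(s, fa) for s, d in zip(singles, doses))
    return CIPoint(ci=float(sum(terms)), terms=terms, fa=float(fa))


def fit_combo_as_single(combo: ComboDataset) -> MedianEffectFit:
    """Median-effect fit of the mixture treated as one agent on TOTAL dose."""
    table = DoseResponseTable(
        drug_id="+".join(combo.component_ids),
        doses=combo.total_doses,
        fa=combo.fa,
    )
    return fit_median_effect(table)


def classify_interaction(
    ci: float, thresholds: tuple[float, float] = SYNERGY_THRESHOLDS
) -> str:
    """Synergistic below the band, additive inside it (closed), antagonistic above."""
    if ci <= 0:
        raise ValueError(f"CI must be positive, got {ci}")
    lower, upper = thresholds
    if not 0 < lower <= upper:
        raise ValueError(f"invalid thresholds {thresholds}")
    if ci < lower:
        return "synergistic"
    if ci <= upper:
        return "additive"
    return "antagonistic"


def ci_table(
    combo: ComboDataset,
    singles: Sequence[MedianEffectFit],
    thresholds: tuple[float, float] = SYNERGY_THRESHOLDS,
) -> CIResult:
    """CI at every observed mixture level, using that level's measured fa.

    Levels with fa exactly 0 or 1 have no finite equivalent single-drug
    dose; they are recorded with a reason and the remaining levels are
    still computed.
    """
    if len(singles) != len(combo.component_ids):
        raise ValueError("one single-drug fit per combination component required")
    for fit, cid in zip(singles, combo.component_ids):
        if fit.drug_id and fit.drug_id != cid:
            raise ValueError(f"single-drug fit order mismatch: {fit.drug_id} vs {cid}")
    levels = []
    for i in range(combo.n_levels):
        fa = float(combo.fa[i])
        total = float(combo.total_doses[i])
        if fa <= 0.0 or fa >= 1.0:
            levels.append(
                CILevel(total, fa, None, (), f"CI undefined at fa={fa}: boundary effect level")
            )
            continue
        point = combination_index_at_point(singles, combo.doses[i], fa)
        levels.append(
            CILevel(total, fa, point.ci, point.terms, classify_interaction(point.ci, thresholds))
        )
    return CIResult(component_ids=combo.component_ids, per_level=tuple(levels))


def ci_at_effect_levels(
    combo_fit: MedianEffectFit,
    singles: Sequence[MedianEffectFit],
    weights: Sequence[float],
    fa_levels: Sequence[float] = (0.50, 0.75, 0.90, 0.95),
) -> EDLevelCI:
    """CI at chosen effect levels (ED50, ED75, ...) from fitted curves.

    For each fa the mixture's own fit supplies the total dose Dt
    producing that effect; Dt is split between components by the design
    weights and compared against each component's solo Dx.
    """
    w = np.asarray(weights, dtype=float)
    if len(singles) != w.size:
        raise ValueError("one weight per single-drug fit required")
    if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-12:
        raise ValueError("weights must be positive and sum to 1")
    cis, totals = [], []
    for fa in fa_levels:
        dt = dose_for_effect(combo_fit, fa)
        point = combination_index_at_point(singles, w * dt, fa)
        cis.append(point.ci)
        totals.append(dt)
    return EDLevelCI(
        fa_levels=tuple(float(f) for f in fa_levels),
        ci_values=tuple(cis),
        total_doses=tuple(totals),
        combo_fit=combo_fit,
    )


def fa_ci_curve(
    combo_fit: MedianEffectFit,
    singles: Sequence[MedianEffectFit],
    weights: Sequence[float],
    fa_grid: Sequence[float],
) -> list[tuple[float, float]]:
    """(fa, CI) pairs over an effect-level grid, ordered by fa."""
    grid = sorted(float(f) for f in fa_grid)
    out = []
    for fa in grid:
        res = ci_at_effect_levels(combo_fit, singles, weights, (fa,))
        out.append((fa, res.ci_values[0]))
    return out
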