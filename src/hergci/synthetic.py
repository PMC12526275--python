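"""Synthetic patch-clamp summary data with the statistical structure the
analysis assumes.

Raw whole-cell recordings are not simulated; the generators produce the
*summary* datasets the pipeline actually consumes — per-cell fractional
blockade at each dose, fixed-ratio combination responses, and gating
curves — so every downstream fitting stage can be exercised, and its
parameter recovery quantified, without any experimental input.

Combination responses are generated under Loewe additivity: at each
total dose the combined fa solves the dose-equivalence condition

    Σ_i (w_i · Dt) / Dx_i(fa) = θ

where Dx_i is component i's median-effect dose-for-effect curve and θ
is an interaction multiplier (θ = 1 additive, θ > 1 antagonistic-like,
θ < 1 synergistic-like).  By construction the combination index
recovered downstream equals θ at every level when no noise is added.

Noise is additive Gaussian on the percent-blockade (or normalized
current) scale, i.i.d. across cells and doses.  All generators require
an explicit seed and are bit-reproducible given one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .combination import ComboDataset
from .dose_response import DoseResponseTable
from .gating import GatingDataset, boltzmann
from .median_effect import MedianEffectFit

__all__ = [
    "SingleDrugSimConfig",
    "ComboComponent",
    "ComboSimConfig",
    "GatingSimConfig",
    "simulate_single_drug",
    "simulate_combination",
    "simulate_gating",
    "loewe_combined_fa",
]

_FA_BRACKET = (1e-9, 1.0 - 1e-9)


def _check_doses(doses: np.ndarray) -> None:
    bad = doses[doses <= 0]
    if bad.size:
        raise ValueError(f"non-positive dose not allowed: {bad[0]} μM")
    if np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be strictly increasing")


@dataclass(frozen=True)
class SingleDrugSimConfig:
    """Ground truth for one drug's concentration-response experiment.

    ``noise_sd`` is the per-cell standard deviation on the
    percent-blockade scale (e.g. 3 means ±3 percentage points).
    """

    drug_id: str
    ic50_true: float  # μM
    hill_n_true: float
    doses: tuple[float, ...]  # μM
    n_cells: int = 8
    noise_sd: float = 3.0  # percent blockade
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        if self.ic50_true <= 0 or self.hill_n_true <= 0:
            raise ValueError("ic50_true and hill_n_true must be positive")
        _check_doses(np.asarray(self.doses))
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ComboComponent:
    """True median-effect parameters (m, Dm) of one mixture component."""

    drug_id: str
    m: float
    dm: float  # μM

    def __post_init__(self) -> None:
        if self.m <= 0 or self.dm <= 0:
            raise ValueError("component m and Dm must be positive")

    def as_fit(self) -> MedianEffectFit:
        """View as a MedianEffectFit so downstream CI code can consume it."""
        return MedianEffectFit(
            m=self.m,
            dm=self.dm,
            r=1.0,
            intercept=-self.m * np.log10(self.dm),
            points_used=2,
            drug_id=self.drug_id,
        )


@dataclass(frozen=True)
class ComboSimConfig:
    """Fixed-ratio combination experiment under Loewe additivity.

    ``interaction_theta`` multiplies the dose-equivalence sum: 1 makes
    the mixture exactly additive (downstream CI = 1), other values are
    recovered as CI = θ.  ``noise_sd`` is on the fa scale.
    """

    components: tuple[ComboComponent, ...]
    weights: tuple[float, ...]
    total_doses: tuple[float, ...]  # μM
    interaction_theta: float = 1.0
    noise_sd: float = 0.0  # fa scale
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        object.__setattr__(self, "total_doses", tuple(float(d) for d in self.total_doses))
        if len(self.components) < 2:
            raise ValueError("a combination needs at least 2 components")
        if len(self.weights) != len(self.components):
            raise ValueError("one weight per component required")
        w = np.asarray(self.weights)
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be positive and sum to 1")
        _check_doses(np.asarray(self.total_doses))
        if self.interaction_theta <= 0:
            raise ValueError("interaction_theta must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GatingSimConfig:
    """Ground truth for one gating-protocol summary curve."""

    kind: str  # one of gating.GATING_KINDS
    grid: tuple[float, ...]  # voltages (mV) or durations (ms)
    v_half: float | None = None  # mV, Boltzmann kinds
    k_slope: float | None = None  # mV, Boltzmann kinds
    tau: float | None = None  # ms, exponential kinds
    noise_sd: float = 0.0  # normalized-current scale
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", tuple(float(g) for g in self.grid))
        grid = np.asarray(self.grid)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.kind.startswith("boltzmann"):
            if self.v_half is None or self.k_slope is None:
                raise ValueError("Boltzmann kinds require v_half and k_slope")
            if self.k_slope <= 0:
                raise ValueError("k_slope must be positive")
        elif self.kind.startswith("exponential"):
            if self.tau is None or self.tau <= 0:
                raise ValueError("exponential kinds require tau > 0")
        else:
            raise ValueError(f"unknown gating kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_single_drug(config: SingleDrugSimConfig) -> DoseResponseTable:
    """Per-cell Hill-curve blockade with Gaussian noise, clamped to [0, 1].

    The returned table carries per-cell fa replicates (one row per dose)
    and their mean in the ``fa`` column.
    """
    rng = np.random.default_rng(config.seed)
    doses = np.asarray(config.doses)
    true_fa = 1.0 / (1.0 + (config.ic50_true / doses) ** config.hill_n_true)
    noise = rng.normal(0.0, config.noise_sd / 100.0, size=(doses.size, config.n_cells))
    cells = np.clip(true_fa[:, None] + noise, 0.0, 1.0)
    return DoseResponseTable(
        drug_id=config.drug_id,
        doses=doses,
        fa=cells.mean(axis=1),
        replicates=cells,
    )


def loewe_combined_fa(
    components: Sequence[ComboComponent],
    weights: Sequence[float],
    total_dose: float,
    theta: float = 1.0,
) -> float:
    """Solve Σ_i (w_i·Dt)/Dx_i(fa) = θ for fa by bracketed root finding.

    The left-hand side is strictly decreasing in fa (each Dx_i grows
    without bound as fa → 1 and vanishes as fa → 0), so the root in
    (0, 1) is unique when it exists.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    w = np.asarray(weights, dtype=float)

    def excess(fa: float) -> float:
        s = sum(
            wi * total_dose / (c.dm * (fa / (1.0 - fa)) ** (1.0 / c.m))
            for wi, c in zip(w, components)
        )
        return s - theta

    lo, hi = _FA_BRACKET
    if excess(lo) < 0 or excess(hi) > 0:
        raise ValueError(
            f"combined fa for total dose {total_dose} μM falls outside the "
            f"bracket [{lo}, {hi}]; dose or parameters are too extreme"
        )
    return float(brentq(excess, lo, hi, xtol=1e-15, rtol=1e-14))


def simulate_combination(config: ComboSimConfig) -> ComboDataset:
    """Fixed-ratio combination responses under (scaled) Loewe additivity."""
    rng = np.random.default_rng(config.seed)
    w = np.asarray(config.weights)
    totals = np.asarray(config.total_doses)
    fa = np.array(
        [
            loewe_combined_fa(config.components, w, dt, config.interaction_theta)
            for dt in totals
        ]
    )
    if config.noise_sd > 0:
        fa = np.clip(fa + rng.normal(0.0, config.noise_sd, size=fa.shape), 0.0, 1.0)
    return ComboDataset(
        component_ids=tuple(c.drug_id for c in config.components),
        weights=w,
        doses=totals[:, None] * w[None, :],
        fa=fa,
        design_label=":".join(["1"] * len(config.components)),
    )


def simulate_gating(config: GatingSimConfig) -> GatingDataset:
    """Noisy gating summary curve.

    Values are *not* clamped to [0, 1]: measured normalized currents can
    overshoot slightly, and the fitters must tolerate that.
    """
    rng = np.random.default_rng(config.seed)
    grid = np.asarray(config.grid)
    if config.kind == "boltzmann_activation":
        y = boltzmann(grid, config.v_half, config.k_slope, "rising")
    elif config.kind == "boltzmann_inactivation":
        y = boltzmann(grid, config.v_half, config.k_slope, "falling")
    elif config.kind == "exponential_rise":
        y = 1.0 - np.exp(-grid / config.tau)
    else:  # exponential_decay
        y = np.exp(-grid / config.tau)
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=y.shape)
    return GatingDataset(kind=config.kind, x=grid, y=y)
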