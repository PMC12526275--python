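"""Published study inputs: mean fractional hERG-current inhibition for
three Fritillaria alkaloids and their fixed-ratio combinations.

These are the measured per-concentration mean blockade fractions (fa)
for peimine, peiminine and sipeimine applied singly, and for the four
fixed-ratio mixtures (three pairwise 1:1 designs and the 1:1:1 triple),
as reported with the original patch-clamp study.  They are the complete
inputs of the combination analysis: every median-effect parameter and
combination index the pipeline produces is recomputed from these
columns.

Doses are μM.  Sipeimine stops at 30 μM (solubility limit), so its
median-effect dose is an extrapolation beyond the tested range.
"""

from __future__ import annotations

import numpy as np

from .combination import ComboDataset
from .dose_response import DoseResponseTable

__all__ = [
    "SINGLE_DRUGS",
    "COMBINATIONS",
    "single_drug_table",
    "combination_dataset",
]

#: drug id -> (doses μM, mean fa)
SINGLE_DRUGS: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "peimine": (
        (1, 3, 10, 30, 100, 300),
        (0.07720, 0.16842, 0.26472, 0.46692, 0.73314, 0.90416),
    ),
    "peiminine": (
        (1, 3, 10, 30, 100, 300),
        (0.06712, 0.16349, 0.32263, 0.4457, 0.62983, 0.79842),
    ),
    "sipeimine": (
        (1, 3, 10, 30),
        (0.12823, 0.23479, 0.32705, 0.4362),
    ),
}

#: component ids -> (per-component doses μM per level, combined fa)
COMBINATIONS: dict[tuple[str, ...], tuple[tuple[tuple[float, ...], ...], tuple[float, ...]]] = {
    ("peimine", "peiminine"): (
        ((1, 1), (3, 3), (10, 10), (30, 30), (100, 100), (150, 150)),
        (0.08071, 0.16318, 0.2766, 0.50934, 0.77468, 0.86801),
    ),
    ("peimine", "sipeimine"): (
        ((1, 1), (3, 3), (10, 10), (30, 30)),
        (0.04072, 0.09928, 0.23001, 0.45886),
    ),
    ("peiminine", "sipeimine"): (
        ((1, 1), (3, 3), (10, 10), (30, 30)),
        (0.1089, 0.20257, 0.31681, 0.46767),
    ),
    ("peimine", "peiminine", "sipeimine"): (
        ((1, 1, 1), (3, 3, 3), (10, 10, 10), (30, 30, 30)),
        (0.09527, 0.20834, 0.36322, 0.58395),
    ),
}


def single_drug_table(drug_id: str) -> DoseResponseTable:
    """Published single-drug dose-effect table for one alkaloid."""
    try:
        doses, fa = SINGLE_DRUGS[drug_id]
    except KeyError:
        raise KeyError(
            f"unknown drug {drug_id!r}; available: {sorted(SINGLE_DRUGS)}"
        ) from None
    return DoseResponseTable(drug_id=drug_id, doses=np.array(doses), fa=np.array(fa))


def combination_dataset(component_ids: tuple[str, ...]) -> ComboDataset:
    """Published fixed-ratio combination dataset for the given components."""
    key = tuple(component_ids)
    try:
        doses, fa = COMBINATIONS[key]
    except KeyError:
        raise KeyError(
            f"unknown combination {key!r}; available: {sorted(COMBINATIONS)}"
        ) from None
    k = len(key)
    return ComboDataset(
        component_ids=key,
        weights=np.full(k, 1.0 / k),
        doses=np.array(doses, dtype=float),
        fa=np.array(fa),
        design_label=":".join(["1"] * k),
    )
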