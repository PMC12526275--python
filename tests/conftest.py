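"""Shared fixtures: published study data and their printed analysis results.

``PRINTED_*`` constants transcribe the values reported with the
original study (median-effect parameters, combination indices); tests
assert that the pipeline recomputes them from the raw fa columns.
"""

import pytest
from hypothesis import settings

from hergci import fit_median_effect

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")
from hergci.datasets import combination_dataset, single_drug_table

# drug -> (m, Dm, r) as printed
PRINTED_SINGLE_PARAMS = {
    "peimine": (0.80527, 26.0768, 0.99184),
    "peiminine": (0.67394, 39.3294, 0.99626),
    "sipeimine": (0.47628, 46.5381, 0.99147),
}

# combination -> (m, Dm, r) of the mixture fitted on total dose
PRINTED_COMBO_PARAMS = {
    ("peimine", "peiminine"): (0.84087, 44.7360, 0.99135),
    ("peimine", "sipeimine"): (0.87461, 75.1683, 0.99962),
    ("peiminine", "sipeimine"): (0.57103, 74.2231, 0.99852),
    ("peimine", "peiminine", "sipeimine"): (0.74823, 58.6535, 0.99874),
}

# combination -> CI per level, in total-dose order
PRINTED_CI = {
    ("peimine", "peiminine"): (1.72625, 1.73871, 2.32422, 1.81993, 1.23432, 0.78784),
    ("peimine", "sipeimine"): (18.2757, 8.38861, 4.43545, 2.32334),
    ("peiminine", "sipeimine"): (2.34913, 1.72776, 1.87398, 1.77044),
    ("peimine", "peiminine", "sipeimine"): (3.77000, 2.21979, 2.05336, 1.53277),
}

# mean blockade and reported Hill parameters (IC50 μM, n)
REPORTED_HILL = {"peimine": (26.1, 0.81), "peiminine": (36.8, 0.64), "sipeimine": (47.6, 0.47)}


@pytest.fixture(scope="session")
def single_fits():
    """Median-effect fits of the three published single-drug tables."""
    return {name: fit_median_effect(single_drug_table(name)) for name in PRINTED_SINGLE_PARAMS}


@pytest.fixture(scope="session")
def combo_datasets():
    return {ids: combination_dataset(ids) for ids in PRINTED_COMBO_PARAMS}
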