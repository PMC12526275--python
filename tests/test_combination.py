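"""Combination-index computation, mixture fitting, and classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hergci import (
    ComboDataset,
    DoseResponseTable,
    ci_at_effect_levels,
    ci_table,
    classify_interaction,
    combination_index_at_point,
    effect_at_dose,
    fa_ci_curve,
    fit_combo_as_single,
    fit_median_effect,
)
from hergci.datasets import combination_dataset, single_drug_table

from conftest import PRINTED_CI, PRINTED_COMBO_PARAMS


def make_fit(m, dm, drug_id=""):
    """MedianEffectFit from bare (m, Dm) parameters."""
    from hergci import MedianEffectFit

    return MedianEffectFit(
        m=m, dm=dm, r=1.0, intercept=-m * np.log10(dm), points_used=2, drug_id=drug_id
    )


class TestCombinationIndexAtPoint:
    def test_printed_two_drug_point(self, single_fits):
        point = combination_index_at_point(
            [single_fits["peimine"], single_fits["peiminine"]], [10.0, 10.0], 0.2766
        )
        assert point.ci == pytest.approx(2.32422, rel=5e-3)
        assert point.ci == pytest.approx(sum(point.terms), abs=1e-12)

    def test_printed_three_drug_point(self, single_fits):
        fits = [single_fits[d] for d in ("peimine", "peiminine", "sipeimine")]
        point = combination_index_at_point(fits, [30.0, 30.0, 30.0], 0.58395)
        assert point.ci == pytest.approx(1.53277, rel=5e-3)

    @pytest.mark.parametrize("total", [1.0, 10.0, 77.7])
    def test_sham_identity(self, single_fits, total):
        # a drug combined with itself at its own effect level: CI = 1
        fit = single_fits["peimine"]
        fa = effect_at_dose(fit, total)
        point = combination_index_at_point([fit, fit], [total / 2, total / 2], fa)
        assert point.ci == pytest.approx(1.0, abs=1e-9)

    def test_removing_component_decreases_ci(self, single_fits):
        fits = [single_fits[d] for d in ("peimine", "peiminine", "sipeimine")]
        full = combination_index_at_point(fits, [30.0, 30.0, 30.0], 0.58395)
        reduced = combination_index_at_point(fits[:2], [30.0, 30.0], 0.58395)
        assert reduced.ci < full.ci

    def test_input_validation(self, single_fits):
        fits = [single_fits["peimine"], single_fits["peiminine"]]
        with pytest.raises(ValueError, match="doses"):
            combination_index_at_point(fits, [10.0], 0.3)
        with pytest.raises(ValueError, match="fa"):
            combination_index_at_point(fits, [10.0, 10.0], 1.0)
        with pytest.raises(ValueError, match="2 or 3"):
            combination_index_at_point(fits * 2, [1.0] * 4, 0.3)


class TestFitComboAsSingle:
    @pytest.mark.parametrize("ids", sorted(PRINTED_COMBO_PARAMS))
    def test_reproduces_printed_mixture_parameters(self, ids, combo_datasets):
        m, dm, r = PRINTED_COMBO_PARAMS[ids]
        fit = fit_combo_as_single(combo_datasets[ids])
        assert fit.m == pytest.approx(m, rel=5e-3)
        assert fit.dm == pytest.approx(dm, rel=5e-3)
        assert fit.r == pytest.approx(r, rel=5e-3)

    def test_sham_combo_recovers_single_drug(self, single_fits):
        # exact median-effect data for one drug presented as a 1:1 self-mix
        fit0 = single_fits["peiminine"]
        totals = np.array([2.0, 10.0, 50.0, 250.0])
        fa = np.array([effect_at_dose(fit0, t) for t in totals])
        combo = ComboDataset(
            component_ids=("peiminine", "peiminine2"),
            weights=np.array([0.5, 0.5]),
            doses=np.column_stack([totals / 2, totals / 2]),
            fa=fa,
        )
        fit = fit_combo_as_single(combo)
        assert fit.m == pytest.approx(fit0.m, rel=1e-9)
        assert fit.dm == pytest.approx(fit0.dm, rel=1e-9)


class TestCITable:
    @pytest.mark.parametrize("ids", sorted(PRINTED_CI))
    def test_reproduces_all_printed_ci_values(self, ids, single_fits, combo_datasets):
        result = ci_table(combo_datasets[ids], [single_fits[d] for d in ids])
        computed = [lv.ci for lv in result.per_level]
        for got, printed in zip(computed, PRINTED_CI[ids]):
            assert got == pytest.approx(printed, rel=5e-3)

    def test_classifications_match_reported_interactions(self, single_fits, combo_datasets):
        # antagonism everywhere except moderate synergism at 150+150
        for ids, combo in combo_datasets.items():
            result = ci_table(combo, [single_fits[d] for d in ids])
            for lv in result.per_level:
                if ids == ("peimine", "peiminine") and lv.total_dose == 300.0:
                    assert lv.interaction == "synergistic"
                else:
                    assert lv.interaction == "antagonistic"

    def test_boundary_fa_level_recorded_not_fatal(self, single_fits):
        combo = ComboDataset(
            component_ids=("peimine", "peiminine"),
            weights=np.array([0.5, 0.5]),
            doses=np.array([[1.0, 1.0], [10.0, 10.0], [100.0, 100.0]]),
            fa=np.array([0.0, 0.3, 0.9]),
        )
        result = ci_table(combo, [single_fits["peimine"], single_fits["peiminine"]])
        assert result.per_level[0].ci is None
        assert "boundary" in result.per_level[0].interaction
        assert result.per_level[1].ci is not None

    def test_component_order_mismatch_rejected(self, single_fits, combo_datasets):
        combo = combo_datasets[("peimine", "peiminine")]
        with pytest.raises(ValueError, match="mismatch"):
            ci_table(combo, [single_fits["peiminine"], single_fits["peimine"]])


class TestEDLevelCI:
    def test_two_drug_ed50_from_printed_parameters(self):
        # closed form: Dt = 44.7360, split 1:1 against the two single Dm
        combo_fit = make_fit(0.84087, 44.7360)
        singles = [make_fit(0.80527, 26.0768), make_fit(0.67394, 39.3294)]
        ed = ci_at_effect_levels(combo_fit, singles, [0.5, 0.5], (0.5,))
        assert ed.ci_values[0] == pytest.approx(1.4265088, rel=1e-6)

    def test_three_drug_ed50_from_printed_parameters(self):
        combo_fit = make_fit(0.74823, 58.6535)
        singles = [
            make_fit(0.80527, 26.0768),
            make_fit(0.67394, 39.3294),
            make_fit(0.47628, 46.5381),
        ]
        ed = ci_at_effect_levels(combo_fit, singles, [1 / 3] * 3, (0.5,))
        assert ed.ci_values[0] == pytest.approx(1.6669775, rel=1e-6)

    def test_sham_combination_ci_one_at_every_level(self, single_fits):
        fit = single_fits["sipeimine"]
        ed = ci_at_effect_levels(fit, [fit, fit], [0.5, 0.5])
        assert np.allclose(ed.ci_values, 1.0, atol=1e-9)

    def test_antagonism_direction_across_effect_levels(self, single_fits, combo_datasets):
        # reported: peiminine+sipeimine antagonism grows with effect
        # level; the other combinations weaken instead
        curves = {}
        for ids, combo in combo_datasets.items():
            singles = [single_fits[d] for d in ids]
            ed = ci_at_effect_levels(fit_combo_as_single(combo), singles, combo.weights)
            curves[ids] = ed.ci_values
        rising = curves[("peiminine", "sipeimine")]
        assert all(a < b for a, b in zip(rising, rising[1:]))
        for ids, cis in curves.items():
            if ids != ("peiminine", "sipeimine"):
                assert all(a > b for a, b in zip(cis, cis[1:]))


class TestFaCICurve:
    def test_sham_curve_is_constant_one(self, single_fits):
        fit = single_fits["peimine"]
        curve = fa_ci_curve(fit, [fit, fit], [0.5, 0.5], np.linspace(0.05, 0.95, 19))
        assert np.allclose([ci for _, ci in curve], 1.0, atol=1e-9)

    def test_single_point_grid_matches_ed_levels(self, single_fits, combo_datasets):
        ids = ("peimine", "sipeimine")
        combo = combo_datasets[ids]
        singles = [single_fits[d] for d in ids]
        combo_fit = fit_combo_as_single(combo)
        curve = fa_ci_curve(combo_fit, singles, combo.weights, [0.75])
        ed = ci_at_effect_levels(combo_fit, singles, combo.weights, (0.75,))
        assert curve == [(0.75, ed.ci_values[0])]

    def test_output_ordered_by_fa(self, single_fits, combo_datasets):
        ids = ("peiminine", "sipeimine")
        combo = combo_datasets[ids]
        singles = [single_fits[d] for d in ids]
        curve = fa_ci_curve(
            fit_combo_as_single(combo), singles, combo.weights, [0.9, 0.2, 0.5]
        )
        assert [fa for fa, _ in curve] == [0.2, 0.5, 0.9]


class TestClassifyInteraction:
    @pytest.mark.parametrize(
        "ci,label",
        [
            (0.78784, "synergistic"),
            (0.89999, "synergistic"),
            (0.90, "additive"),
            (1.0, "additive"),
            (1.10, "additive"),
            (1.10001, "antagonistic"),
            (2.32422, "antagonistic"),
        ],
    )
    def test_band_membership(self, ci, label):
        assert classify_interaction(ci) == label

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            classify_interaction(0.0)


class TestComboDatasetValidation:
    def test_ratio_violation_names_level(self):
        with pytest.raises(ValueError, match="level 1"):
            ComboDataset(
                component_ids=("a", "b"),
                weights=np.array([0.5, 0.5]),
                doses=np.array([[1.0, 1.0], [1.0, 2.0]]),
                fa=np.array([0.2, 0.4]),
            )

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ComboDataset(
                component_ids=("a", "b"),
                weights=np.array([0.6, 0.6]),
                doses=np.array([[1.0, 1.0]]),
                fa=np.array([0.2]),
            )


@given(
    m=st.floats(0.3, 3.0),
    dm=st.floats(1.0, 200.0),
    total=st.floats(0.5, 500.0),
)
@settings(max_examples=100)
def test_sham_ci_identity_property(m, dm, total):
    """CI of any drug with itself is exactly 1 at its own effect level."""
    fit = make_fit(m, dm)
    fa = effect_at_dose(fit, total)
    point = combination_index_at_point([fit, fit], [total / 2, total / 2], fa)
    assert point.ci == pytest.approx(1.0, abs=1e-9)
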