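"""One-way deterministic sensitivity analysis."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqcost import (
    ItemSelector,
    ScenarioSpec,
    apply_scenario,
    component_cost,
    cross_project_sensitivity,
    per_patient_breakdown,
    relative_total_change,
    tornado,
    tornado_frame,
)
from seqcost.sensitivity import SelectorError, default_scenarios

LIBSEQ = ScenarioSpec(
    name="libseq",
    selector=ItemSelector(steps=("library_preparation", "sequencing")),
    factor=0.9,
)
LABOUR = ScenarioSpec(
    name="labour", selector=ItemSelector(cost_type="labour"), factor=1.2
)
STORAGE_REGIONAL = ScenarioSpec(
    name="storage", selector=ItemSelector(steps=("data_storage",)), factor=2.5
)


class TestApplyScenario:
    def test_identity_factor_leaves_totals_unchanged(self, projects):
        project = projects["breast_panel"]
        same = apply_scenario(project, LIBSEQ, factor=1.0)
        assert per_patient_breakdown(same).total_incl_capital == pytest.approx(
            per_patient_breakdown(project).total_incl_capital
        )

    def test_original_project_is_untouched(self, projects):
        project = projects["breast_panel"]
        before = per_patient_breakdown(project).total_incl_capital
        apply_scenario(project, LIBSEQ)
        assert per_patient_breakdown(project).total_incl_capital == before

    def test_storage_times_2p5_on_breast_panel(self, projects):
        modified = apply_scenario(projects["breast_panel"], STORAGE_REGIONAL)
        storage = [i for i in modified.items if i.step.value == "data_storage"]
        assert component_cost(storage[0]) == pytest.approx(4.90, abs=0.005)

    def test_libseq_cut_on_oesophageal_genome(self, projects):
        modified = apply_scenario(projects["oesophageal_genome"], LIBSEQ)
        seq = [i for i in modified.items if i.merged]
        assert component_cost(seq[0]) == pytest.approx(3769.74, abs=0.005)

    def test_empty_selection_raises_naming_the_selector(self, projects):
        scenario = ScenarioSpec(
            name="ghost",
            selector=ItemSelector(label_pattern="no-such-item"),
            factor=0.5,
        )
        with pytest.raises(SelectorError, match="ghost"):
            apply_scenario(projects["breast_panel"], scenario)

    def test_absolute_replacement(self, projects):
        scenario = ScenarioSpec(
            name="flat-storage",
            selector=ItemSelector(steps=("data_storage",)),
            set_to=10.0,
        )
        modified = apply_scenario(projects["oesophageal_genome"], scenario)
        storage = [i for i in modified.items if i.step.value == "data_storage"]
        assert component_cost(storage[0]) == 10.0

    def test_capital_selector_scales_equipment(self, projects):
        scenario = ScenarioSpec(
            name="capital", selector=ItemSelector(capital=True), factor=1.2
        )
        modified = apply_scenario(projects["breast_panel"], scenario)
        base = per_patient_breakdown(projects["breast_panel"])
        perturbed = per_patient_breakdown(modified)
        assert perturbed.capital_per_patient == pytest.approx(
            1.2 * base.capital_per_patient
        )
        assert perturbed.total_excl_capital == pytest.approx(base.total_excl_capital)


class TestRelativeChange:
    def test_identity_scenario_changes_nothing(self, projects):
        assert relative_total_change(
            projects["lung_exome"], LIBSEQ, factor=1.0
        ) == pytest.approx(0.0)

    def test_libseq_cut_on_lung_melanoma_panel(self, projects):
        # -10% on a 329.32 component of a 462.26 capital-inclusive total
        change = relative_total_change(projects["lung_melanoma_panel"], LIBSEQ)
        assert change == pytest.approx(-7.1, abs=0.05)

    def test_storage_regional_tier_on_genomes_and_panels(self, projects):
        assert relative_total_change(
            projects["oesophageal_genome"], STORAGE_REGIONAL
        ) == pytest.approx(6.6, abs=0.05)
        for name in ("lung_melanoma_panel", "breast_panel"):
            assert relative_total_change(projects[name], STORAGE_REGIONAL) <= 0.8
        assert relative_total_change(
            projects["lung_exome"], STORAGE_REGIONAL
        ) == pytest.approx(2.0, abs=0.05)

    def test_component_share_linearity_oracle(self, cohort):
        # relative change = (factor - 1) x component share of the
        # capital-inclusive total, for every synthetic project
        factor = 0.75
        for project in cohort[:50]:
            base = per_patient_breakdown(project)
            labour = sum(
                component_cost(i) for i in project.items
                if i.cost_type.value == "labour"
            )
            expected = 100.0 * (factor - 1.0) * labour / base.total_incl_capital
            observed = relative_total_change(project, LABOUR, factor=factor)
            assert observed == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        pct=st.floats(min_value=0.01, max_value=0.99),
        idx=st.integers(min_value=0, max_value=199),
    )
    def test_symmetry_of_opposite_perturbations(self, cohort, pct, idx):
        project = cohort[idx]
        up = relative_total_change(project, LABOUR, factor=1.0 + pct)
        down = relative_total_change(project, LABOUR, factor=1.0 - pct)
        assert up == pytest.approx(-down, abs=1e-9)


class TestCrossProjectSensitivity:
    def test_libseq_price_cuts_mean_decreases(self, project_list):
        for factor, expected in ((0.9, -7.2), (0.8, -14.4), (0.7, -21.6)):
            summary = cross_project_sensitivity(project_list, LIBSEQ, factor=factor)
            assert summary.mean == pytest.approx(expected, abs=0.05)

    def test_labour_pm_20pct_spans_published_range(self, project_list):
        summary = cross_project_sensitivity(project_list, LABOUR, factor=1.2)
        assert summary.min == pytest.approx(0.5, abs=0.05)
        assert summary.max == pytest.approx(5.4, abs=0.05)

    def test_identity_scenario_is_all_zero(self, project_list):
        summary = cross_project_sensitivity(project_list, LIBSEQ, factor=1.0)
        assert summary.mean == summary.min == summary.max == 0.0

    def test_empty_project_list_rejected(self):
        with pytest.raises(ValueError):
            cross_project_sensitivity([], LIBSEQ)


class TestTornado:
    def test_libseq_has_largest_swing_on_oesophageal_genome(self, projects):
        rows = tornado(projects["oesophageal_genome"], default_scenarios())
        assert rows[0].parameter == "library_prep_and_sequencing_price"
        assert all(
            rows[i].swing >= rows[i + 1].swing for i in range(len(rows) - 1)
        )

    def test_single_scenario_swing(self, projects):
        scenario = ScenarioSpec(
            name="labour",
            selector=ItemSelector(cost_type="labour"),
            low=0.8,
            high=1.2,
        )
        (row,) = tornado(projects["breast_panel"], [scenario])
        assert row.swing == pytest.approx(abs(row.total_high - row.total_low))
        assert row.total_low <= row.baseline_total <= row.total_high

    def test_all_identity_scenarios_tie_break_alphabetically(self, projects):
        scenarios = [
            ScenarioSpec(name=name, selector=ItemSelector(cost_type="labour"),
                         factor=1.0)
            for name in ("zeta", "alpha", "mid")
        ]
        rows = tornado(projects["breast_panel"], scenarios)
        assert [r.parameter for r in rows] == ["alpha", "mid", "zeta"]
        assert all(r.swing == 0.0 for r in rows)

    def test_deterministic_repeatable_output(self, projects):
        frame_a = tornado_frame(tornado(projects["lung_exome"], default_scenarios()))
        frame_b = tornado_frame(tornado(projects["lung_exome"], default_scenarios()))
        assert frame_a.equals(frame_b)
        assert frame_a.to_csv() == frame_b.to_csv()

    def test_no_scenarios_rejected(self, projects):
        with pytest.raises(ValueError):
            tornado(projects["breast_panel"], [])
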