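"""Component formulas, composition, blending, and engine-wide properties."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radstaff import (
    CaseMix,
    CenterInventory,
    EducationProfile,
    EquipmentInventory,
    PanelSpec,
    RoleVector,
    administration_fte,
    blend_roles,
    clinical_equipment_fte,
    clinical_procedures_fte,
    core_services_fte,
    education_fte,
    estimate_staffing,
    fte_to_hours,
    generate_center,
)
from radstaff.roles import ROLES

from ._oracle import oracle_totals


def approx_vec(vec, expected, abs=1e-12):
    assert vec.as_tuple() == pytest.approx(expected, abs=abs)


class TestClinicalProcedures:
    def test_default_mix_per_1000_cases(self, table):
        mix = CaseMix(total_cases=1000, complex_cases=250, specialized_cases=10)
        proc = clinical_procedures_fte(mix, table)
        assert proc.physicist == pytest.approx(0.775)
        # ~1.5 h of physicist time per external-beam case
        assert fte_to_hours(proc.physicist, table) / 1000 == pytest.approx(1.51125)

    def test_zero_mix_gives_zero_vector(self, table):
        assert clinical_procedures_fte(CaseMix(total_cases=0), table) == RoleVector()

    def test_hand_summed_row_products(self, table):
        mix = CaseMix(
            total_cases=2000, complex_cases=500, specialized_cases=20,
            brachy_fractions=200,
        )
        proc = clinical_procedures_fte(mix, table)
        assert proc.physicist == pytest.approx(1.0 + 0.5 + 0.05 + 0.4)
        assert proc.assistant == pytest.approx(0.4 + 0.25 + 0.024 + 0.10)


class TestClinicalEquipment:
    def test_single_linac_with_overheads(self, table):
        eq = EquipmentInventory(linac=1, qa_program=False, regulated_items=0)
        vec = clinical_equipment_fte(eq, table)
        # base 0.20 + procurement 0.02*0.20 + training 0.02*(1 MV + 0 TPS)
        assert vec.physicist == pytest.approx(0.224)
        assert vec.elec == pytest.approx(0.25)
        assert vec.it == pytest.approx(0.03)

    def test_empty_inventory_zero_vector(self, table):
        eq = EquipmentInventory(qa_program=False, regulated_items=0)
        assert clinical_equipment_fte(eq, table) == RoleVector()

    def test_four_linac_center_spreadsheet_total(self, table):
        eq = EquipmentInventory(
            linac=4, simulator=1, tps_system=1, rois_system=1,
            secondary_calc_system=1, qa_program=True, regulated_items=4,
        )
        vec = clinical_equipment_fte(eq, table)
        # base 1.35 + procurement 0.027 + licensing 0.10 + training 0.10
        assert vec.physicist == pytest.approx(1.577)


class TestCoreServices:
    def test_twenty_percent_plus_oversight(self, table):
        core = core_services_fte(
            RoleVector(physicist=1.1625), RoleVector(physicist=1.577),
            CaseMix(total_cases=1500), table,
        )
        assert core.physicist == pytest.approx(0.2 * 2.7395 + 0.06)
        assert core.assistant == core.elec == core.mech == core.it == 0.0

    def test_zero_inputs_zero_vector(self, table):
        core = core_services_fte(
            RoleVector(), RoleVector(), CaseMix(total_cases=0), table
        )
        assert core == RoleVector()

    def test_fraction_override_scales_linearly(self, table):
        args = (RoleVector(physicist=2.0), RoleVector(physicist=1.0),
                CaseMix(total_cases=1000), table)
        base = core_services_fte(*args)
        raised = core_services_fte(*args, fraction=0.3)
        assert raised.physicist - base.physicist == pytest.approx(0.1 * 3.0)
        assert raised.assistant == 0.0

    def test_fraction_out_of_range(self, table):
        with pytest.raises(ValueError):
            core_services_fte(
                RoleVector(), RoleVector(), CaseMix(total_cases=0), table,
                fraction=1.5,
            )


class TestEducation:
    def test_single_resident_includes_program_baseline(self, table):
        vec = education_fte(EducationProfile(physics_residents=1), table)
        assert vec.physicist == pytest.approx(0.1 + 0.1)
        assert vec.assistant == pytest.approx(0.025)

    def test_empty_profile_no_baselines_fire(self, table):
        assert education_fte(EducationProfile(), table) == RoleVector()

    def test_term_by_term_mixed_profile(self, table):
        vec = education_fte(
            EducationProfile(grad_students=2, courses=1, therapy_students=3),
            table,
        )
        # 2*0.1 + baseline 0.1 + 0.06 + 3*0.02
        assert vec.physicist == pytest.approx(0.42)
        assert vec.assistant == pytest.approx(2 * 0.025 + 3 * 0.005)


class TestAdministration:
    def test_supervision_and_coverage_contract(self, table):
        admin = administration_fte(RoleVector(4.0, 1.5, 1.5, 0.3, 0.6), table)
        supervision = 0.05 * 4.0 + 0.02 * (1.5 + 1.5 + 0.3 + 0.6)
        assert admin.physicist == pytest.approx(supervision + 0.1 * (4.0 + supervision))
        assert admin.assistant == pytest.approx(0.15)
        assert admin.it == pytest.approx(0.06)

    def test_zero_vector_in_zero_out(self, table):
        assert administration_fte(RoleVector(), table) == RoleVector()

    def test_single_role_closed_form(self, table):
        admin = administration_fte(RoleVector(physicist=1.0), table)
        assert admin.physicist == pytest.approx(0.05 + 0.10 * 1.05)

    def test_negative_input_rejected(self, table):
        with pytest.raises(ValueError):
            administration_fte(RoleVector(physicist=-1.0), table)


class TestEstimateStaffing:
    def test_empty_inventory_all_zero(self, table):
        inv = CenterInventory(
            center_id="empty",
            case_mix=CaseMix(total_cases=0),
            equipment=EquipmentInventory(qa_program=False, regulated_items=0),
        )
        est = estimate_staffing(inv, table)
        assert est.totals == RoleVector()

    def test_totals_are_component_sums(self, table, synthetic_inventories):
        for inv in synthetic_inventories[:10]:
            est = estimate_staffing(inv, table)
            summed = (est.procedures + est.equipment + est.core_services
                      + est.education + est.administration)
            approx_vec(est.totals, summed.as_tuple())

    def test_terms_reconstruct_totals(self, table, synthetic_inventories):
        est = estimate_staffing(synthetic_inventories[0], table)
        by_role = {role: 0.0 for role in ROLES}
        for t in est.terms:
            by_role[t.role] += t.value
        for role in ROLES:
            assert by_role[role] == pytest.approx(est.totals.get(role))

    def test_oracle_equivalence_on_synthetic_centers(self, table, synthetic_inventories):
        """Engine totals match an independent flat spreadsheet recompute."""
        for inv in synthetic_inventories:
            est = estimate_staffing(inv, table)
            expected = oracle_totals(inv, table)
            for role in ROLES:
                assert abs(est.totals.get(role) - expected[role]) < 1e-9

    def test_monotone_in_inventory_counts(self, table):
        """Adding any single item never decreases any role's total."""
        spec = PanelSpec(n_centers=1, seed=99)
        inv = generate_center(spec, 0)
        base = estimate_staffing(inv, table).totals
        bumps = [
            lambda i: i.model_copy(update={"case_mix": i.case_mix.model_copy(
                update={"total_cases": i.case_mix.total_cases + 100})}),
            lambda i: i.model_copy(update={"case_mix": i.case_mix.model_copy(
                update={"brachy_fractions": i.case_mix.brachy_fractions + 50})}),
            lambda i: i.model_copy(update={"equipment": i.equipment.model_copy(
                update={"linac": i.equipment.linac + 1})}),
            lambda i: i.model_copy(update={"equipment": i.equipment.model_copy(
                update={"mr_linac": i.equipment.mr_linac + 1})}),
            lambda i: i.model_copy(update={"equipment": i.equipment.model_copy(
                update={"tps_system": i.equipment.tps_system + 1})}),
            lambda i: i.model_copy(update={"education": i.education.model_copy(
                update={"grad_students": i.education.grad_students + 1})}),
        ]
        for bump in bumps:
            bumped = estimate_staffing(bump(inv), table).totals
            for role in ROLES:
                assert bumped.get(role) >= base.get(role) - 1e-12

    @given(
        total=st.floats(0, 10000),
        cfrac=st.floats(0, 0.5),
        sfrac=st.floats(0, 0.1),
        brachy=st.floats(0, 2000),
        scale=st.floats(0.1, 3.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_procedures_homogeneous_degree_one(self, table, total, cfrac, sfrac, brachy, scale):
        """Doubling every case-mix count doubles the procedures component."""
        mix = CaseMix(
            total_cases=total, complex_cases=cfrac * total,
            specialized_cases=sfrac * total, brachy_fractions=brachy,
        )
        scaled = CaseMix(
            total_cases=scale * total, complex_cases=scale * cfrac * total,
            specialized_cases=scale * sfrac * total,
            brachy_fractions=scale * brachy,
        )
        one = clinical_procedures_fte(mix, table)
        two = clinical_procedures_fte(scaled, table)
        for role in ROLES:
            assert two.get(role) == pytest.approx(scale * one.get(role), rel=1e-9, abs=1e-12)

    def test_procedures_additive_in_case_counts(self, table):
        """With equipment fixed, procedures is linear: f(a) + f(b) = f(a+b)."""
        a = CaseMix(total_cases=1000, complex_cases=200, specialized_cases=10,
                    brachy_fractions=50)
        b = CaseMix(total_cases=500, complex_cases=100, specialized_cases=5,
                    brachy_fractions=25)
        ab = CaseMix(total_cases=1500, complex_cases=300, specialized_cases=15,
                     brachy_fractions=75)
        lhs = clinical_procedures_fte(a, table) + clinical_procedures_fte(b, table)
        approx_vec(clinical_procedures_fte(ab, table), lhs.as_tuple())


class TestBlendRoles:
    def test_identity_mapping_unchanged(self, table, synthetic_inventories):
        est = estimate_staffing(synthetic_inventories[0], table)
        blended = blend_roles(est, {"physicist": "physicist"})
        assert blended.totals == est.totals

    def test_assistant_merged_into_physicist(self, table, synthetic_inventories):
        est = estimate_staffing(synthetic_inventories[1], table)
        blended = blend_roles(est, {"assistant": "physicist"})
        assert blended.totals.physicist == pytest.approx(
            est.totals.physicist + est.totals.assistant
        )
        assert blended.totals.assistant == 0.0

    def test_grand_total_conserved_any_mapping(self, table, synthetic_inventories):
        est = estimate_staffing(synthetic_inventories[2], table)
        for mapping in ({"assistant": "physicist"}, {"mech": "elec", "it": "elec"}):
            blended = blend_roles(est, mapping)
            assert blended.totals.total() == pytest.approx(est.totals.total())

    def test_unknown_role_rejected(self, table, synthetic_inventories):
        est = estimate_staffing(synthetic_inventories[0], table)
        with pytest.raises(KeyError):
            blend_roles(est, {"dosimetrist": "physicist"})

    def test_blend_option_applied_by_estimate(self, table, synthetic_inventories):
        inv = synthetic_inventories[3]
        blended_inv = inv.model_copy(update={
            "options": inv.options.model_copy(
                update={"blend_assistant_into_physicist": True})
        })
        plain = estimate_staffing(inv, table)
        auto = estimate_staffing(blended_inv, table)
        assert auto.totals.assistant == 0.0
        assert auto.totals.physicist == pytest.approx(
            plain.totals.physicist + plain.totals.assistant
        )


class TestFteToHours:
    def test_one_fte_is_work_year(self, table):
        assert fte_to_hours(1.0, table) == 1950.0

    def test_zero(self, table):
        assert fte_to_hours(0.0, table) == 0.0

    def test_negative_rejected(self, table):
        with pytest.raises(ValueError):
            fte_to_hours(-0.5, table)
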