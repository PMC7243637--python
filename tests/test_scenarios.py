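import json
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hctnomo.core import PatientProfile, blood_volume, hct_after_blood_loss
from hctnomo.errors import EventError, ValidationError
from hctnomo.scenarios import (
    DEHYDRATION_BASELINE_HCT,
    FluidEvent,
    apply_events,
    estimate_blood_loss,
    estimate_fluid_deficit,
    load_scenario,
    reference_scenarios,
    result_to_dict,
    scenario_from_dict,
)


class TestFluidEvent:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            FluidEvent("bleeding", 100.0)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValidationError):
            FluidEvent("blood_loss", -5.0)

    def test_donor_hct_only_for_whole_blood(self):
        with pytest.raises(ValidationError):
            FluidEvent("crystalloid_in", 100.0, donor_hct_pct=40.0)
        FluidEvent("whole_blood_in", 100.0, donor_hct_pct=40.0)  # fine

    def test_donor_hct_range(self):
        with pytest.raises(ValidationError):
            FluidEvent("whole_blood_in", 100.0, donor_hct_pct=101.0)


class TestApplyEvents:
    def test_loss_then_equilibrate_matches_closed_form(self, infant_12kg):
        res = apply_events(
            infant_12kg, 35.0,
            [FluidEvent("blood_loss", 200.0), FluidEvent("equilibrate_to_baseline")],
        )
        assert res.final_hct_pct == pytest.approx(245.0 / 9.0)
        assert res.final.bv_ml == pytest.approx(900.0)

    def test_loss_plus_crystalloid(self, infant_12kg):
        res = apply_events(
            infant_12kg, 35.0,
            [FluidEvent("blood_loss", 200.0), FluidEvent("crystalloid_in", 400.0)],
        )
        assert res.final.bv_ml == pytest.approx(1100.0)
        assert res.final.rbc_ml == pytest.approx(245.0)
        assert res.final_hct_pct == pytest.approx(245.0 / 11.0)

    def test_empty_event_list_is_identity(self, infant_6kg):
        res = apply_events(infant_6kg, 42.0, [])
        assert res.final_hct_pct == pytest.approx(42.0)
        assert res.trajectory == ()

    def test_trajectory_length_and_audit(self, infant_12kg):
        events = [FluidEvent("blood_loss", 100.0), FluidEvent("crystalloid_in", 50.0),
                  FluidEvent("urine_out", 30.0)]
        res = apply_events(infant_12kg, 35.0, events)
        assert len(res.trajectory) == 3
        assert len(res.audit) == 3
        assert res.audit[0].startswith("[0] blood_loss")

    def test_whole_blood_defaults_to_initial_hct(self, infant_12kg):
        # transfusing whole blood at the patient's own hct undoes an equal loss
        res = apply_events(
            infant_12kg, 35.0,
            [FluidEvent("blood_loss", 200.0), FluidEvent("whole_blood_in", 200.0)],
        )
        assert res.final_hct_pct == pytest.approx(35.0)
        assert res.final.bv_ml == pytest.approx(900.0)

    def test_whole_blood_donor_override(self, infant_12kg):
        res = apply_events(
            infant_12kg, 35.0, [FluidEvent("whole_blood_in", 100.0, donor_hct_pct=60.0)]
        )
        assert res.final.rbc_ml == pytest.approx(315.0 + 60.0)
        assert res.final.bv_ml == pytest.approx(1000.0)

    def test_packed_cells(self, infant_12kg, config):
        res = apply_events(infant_12kg, 35.0, [FluidEvent("packed_rbc_in", 100.0)], config)
        assert res.final.bv_ml == pytest.approx(1000.0)
        assert res.final.rbc_ml == pytest.approx(315.0 + 65.0)

    def test_offending_event_index_reported(self, infant_6kg):
        events = [FluidEvent("crystalloid_in", 100.0), FluidEvent("blood_loss", 10000.0)]
        with pytest.raises(EventError) as exc:
            apply_events(infant_6kg, 35.0, events)
        assert exc.value.index == 1

    def test_dehydration_cannot_exceed_plasma(self, infant_6kg):
        with pytest.raises(EventError) as exc:
            apply_events(infant_6kg, 50.0, [FluidEvent("dehydration", 300.0)])
        assert exc.value.index == 0

    def test_order_sensitivity(self, infant_12kg):
        """Loss-then-fluid removes more red cells than fluid-then-loss."""
        loss_first = apply_events(
            infant_12kg, 35.0,
            [FluidEvent("blood_loss", 200.0), FluidEvent("crystalloid_in", 400.0)],
        )
        fluid_first = apply_events(
            infant_12kg, 35.0,
            [FluidEvent("crystalloid_in", 400.0), FluidEvent("blood_loss", 200.0)],
        )
        # regression-pinned values: both end at bv 1100 ml, but rbc differs
        assert loss_first.final.rbc_ml == pytest.approx(245.0)
        assert fluid_first.final.rbc_ml == pytest.approx(315.0 - 200.0 * (315.0 / 1300.0))
        assert fluid_first.final_hct_pct > loss_first.final_hct_pct

    def test_equilibrate_after_dilution_restores_baseline_bv(self, infant_6kg):
        res = apply_events(
            infant_6kg, 35.0,
            [FluidEvent("crystalloid_in", 300.0), FluidEvent("equilibrate_to_baseline")],
        )
        assert res.final.bv_ml == pytest.approx(450.0)
        assert res.final_hct_pct == pytest.approx(35.0)

    @given(
        st.floats(min_value=1.0, max_value=150.0),
        st.floats(min_value=5.0, max_value=85.0),
        st.lists(
            st.sampled_from(["crystalloid_in", "urine_out", "insensible_out", "dehydration"]),
            max_size=6,
        ),
    )
    def test_rbc_conserved_without_cell_events(self, weight, hct, kinds):
        """Pure fluid shifts never change the red-cell tally."""
        profile = PatientProfile(weight_kg=weight)
        bv0 = blood_volume(profile)
        rbc0 = bv0 * hct / 100.0
        # small volumes so the state stays valid for any ordering
        events = [FluidEvent(k, bv0 * 0.01) for k in kinds]
        res = apply_events(profile, hct, events)
        assert res.final.rbc_ml == rbc0  # exact: no arithmetic touches rbc

    def test_matches_closed_form_on_random_inputs(self):
        rng = random.Random(7780)
        for _ in range(500):
            weight = rng.uniform(1.0, 150.0)
            hct = rng.uniform(5.0, 95.0)
            profile = PatientProfile(weight_kg=weight)
            bv0 = blood_volume(profile)
            lost = rng.uniform(0.0, bv0 * 0.9)
            res = apply_events(
                profile, hct,
                [FluidEvent("blood_loss", lost), FluidEvent("equilibrate_to_baseline")],
            )
            assert res.final_hct_pct == pytest.approx(
                hct_after_blood_loss(hct, bv0, lost), rel=1e-12
            )


class TestEstimateBloodLoss:
    def test_worked_example(self, infant_12kg):
        assert estimate_blood_loss(infant_12kg, 35.0, 245.0 / 9.0) == pytest.approx(200.0)

    def test_no_drop_no_loss(self, infant_12kg):
        assert estimate_blood_loss(infant_12kg, 35.0, 35.0) == 0.0

    def test_half_hct_half_volume(self, infant_12kg):
        assert estimate_blood_loss(infant_12kg, 35.0, 17.5) == pytest.approx(450.0)

    def test_rise_rejected(self, infant_12kg):
        with pytest.raises(ValidationError):
            estimate_blood_loss(infant_12kg, 30.0, 35.0)

    @given(
        st.floats(min_value=1.0, max_value=150.0),
        st.floats(min_value=5.0, max_value=95.0),
        st.floats(min_value=0.0, max_value=0.95),
    )
    def test_inverse_of_forward_model(self, weight, hct, frac):
        profile = PatientProfile(weight_kg=weight)
        bv = blood_volume(profile)
        lost = bv * frac
        post = hct_after_blood_loss(hct, bv, lost)
        assert estimate_blood_loss(profile, hct, post) == pytest.approx(
            lost, rel=1e-6, abs=1e-6
        )


class TestEstimateFluidDeficit:
    def test_two_kg_difference_is_two_litres(self):
        # pick hct pair whose ratio forces weight_pre = weight_now + 2
        est = estimate_fluid_deficit(6.0, 35.0 * 8.0 / 6.0, 35.0)
        assert est.deficit_l == pytest.approx(2.0)
        assert est.weight_pre_kg == pytest.approx(8.0)

    def test_worked_example(self):
        est = estimate_fluid_deficit(6.0, 50.0, 35.0)
        assert est.weight_pre_kg == pytest.approx(60.0 / 7.0)  # 8.571428...
        assert est.deficit_l == pytest.approx(18.0 / 7.0)  # 2.571428...
        assert not est.fluid_gain

    def test_no_change(self):
        est = estimate_fluid_deficit(10.0, 40.0, 40.0)
        assert est.deficit_l == pytest.approx(0.0)

    def test_fluid_gain_flagged_not_raised(self):
        est = estimate_fluid_deficit(10.0, 30.0, 40.0)
        assert est.fluid_gain
        assert est.deficit_l < 0

    def test_validation(self):
        with pytest.raises(ValidationError):
            estimate_fluid_deficit(0.0, 40.0, 40.0)
        with pytest.raises(ValidationError):
            estimate_fluid_deficit(5.0, 0.0, 40.0)

    @given(
        st.floats(min_value=2.0, max_value=150.0),
        st.floats(min_value=10.0, max_value=60.0),
        st.floats(min_value=0.0, max_value=0.5),
    )
    def test_dehydration_round_trip(self, w0, h0, frac):
        """Removing D kg of water then back-calculating recovers D."""
        bv_per_kg = 75.0
        plasma_limit = w0 * (1.0 - h0 / 100.0) * 0.9  # stay clear of the boundary
        d = frac * plasma_limit
        hct_now = h0 * w0 / (w0 - d)
        est = estimate_fluid_deficit(w0 - d, hct_now, h0, bv_per_kg=bv_per_kg)
        assert est.deficit_l == pytest.approx(d, rel=1e-9, abs=1e-9)


class TestReferenceScenarios:
    def test_count(self):
        assert len(reference_scenarios()) == 4

    def test_names_unique(self):
        names = [s.name for s in reference_scenarios()]
        assert len(set(names)) == 4

    def test_expected_values(self):
        by_name = {s.name: s for s in reference_scenarios()}
        assert by_name["loss-equilibrated"].expected["final_hct_pct"] == pytest.approx(245.0 / 9.0)
        assert by_name["infusion"].expected["final_hct_pct"] == pytest.approx(315.0 / 13.0)
        assert by_name["loss-and-crystalloid"].expected["final_hct_pct"] == pytest.approx(
            245.0 / 11.0
        )
        assert by_name["dehydration-deficit"].expected["deficit_l"] == pytest.approx(18.0 / 7.0)

    def test_event_scenarios_replay_through_engine(self):
        for s in reference_scenarios():
            if not s.events:
                continue
            res = apply_events(s.profile, s.initial_hct_pct, list(s.events))
            assert res.final_hct_pct == pytest.approx(s.expected["final_hct_pct"])

    def test_deficit_scenario_baseline_is_explicit(self):
        s = {x.name: x for x in reference_scenarios()}["dehydration-deficit"]
        assert s.baseline_hct_pct == DEHYDRATION_BASELINE_HCT == 35.0


class TestScenarioJson:
    GOOD = {
        "weight_kg": 12,
        "initial_hct_pct": 35,
        "events": [
            {"kind": "blood_loss", "volume_ml": 200},
            {"kind": "crystalloid_in", "volume_ml": 400},
        ],
    }

    def test_round_trip_through_file(self, tmp_path):
        path = tmp_path / "scenario.json"
        path.write_text(json.dumps(self.GOOD))
        profile, hct_i, events = load_scenario(path)
        res = apply_events(profile, hct_i, events)
        assert res.final_hct_pct == pytest.approx(245.0 / 11.0)

    def test_missing_field(self):
        with pytest.raises(ValidationError, match="initial_hct_pct"):
            scenario_from_dict({"weight_kg": 12, "events": []})

    def test_unknown_top_level_field(self):
        doc = dict(self.GOOD, extra=1)
        with pytest.raises(ValidationError, match="unknown fields"):
            scenario_from_dict(doc)

    def test_unknown_event_field(self):
        doc = dict(self.GOOD, events=[{"kind": "blood_loss", "ml": 5}])
        with pytest.raises(ValidationError, match=r"events\[0\]"):
            scenario_from_dict(doc)

    def test_bad_json_file(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ValidationError, match="not valid JSON"):
            load_scenario(path)

    def test_result_to_dict_is_serializable(self, infant_12kg):
        res = apply_events(infant_12kg, 35.0, [FluidEvent("blood_loss", 100.0)])
        doc = result_to_dict(res)
        json.dumps(doc)
        assert doc["final_hct_pct"] == pytest.approx(res.final_hct_pct)
        assert len(doc["trajectory"]) == 1
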