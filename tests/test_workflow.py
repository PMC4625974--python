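"""Scan workflow: reference state, C1/C2 perturbation solves, classification."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from fluxsum import (ATTENUATION, INTENSIFICATION, FluxSumRecord,
                     flux_sum_extrema, growth_under_perturbation,
                     production_profile, reference_state, scan,
                     worst_case_production)
from fluxsum.workflow import (DegenerateRangeError, adverse_sense,
                              perturbation_bound)


def record_for(model, ref, met_id):
    return FluxSumRecord(met_id, ref.phi_wt[met_id],
                         *flux_sum_extrema(model, met_id))


class TestReferenceState:
    def test_two_branch_reference(self, two_branch):
        ref = reference_state(two_branch, "EX_E", "maximize")
        assert ref.wt_growth == pytest.approx(10.0, abs=1e-9)
        assert ref.wt_production == pytest.approx(0.0, abs=1e-9)
        assert ref.phi_wt["C"] == pytest.approx(10.0, abs=1e-6)
        assert ref.phi_wt["B"] == pytest.approx(0.0, abs=1e-6)

    def test_zero_growth_model_still_produces_reference(self, two_branch):
        frozen = two_branch.copy()
        biomass = frozen.reaction("BIOMASS")
        biomass.lower_bound = biomass.upper_bound = 0.0
        ref = reference_state(frozen, "EX_E", "maximize")
        assert ref.wt_growth == pytest.approx(0.0, abs=1e-9)
        # at zero growth the uptake must exit somewhere; Phi values must be
        # consistent with some feasible zero-growth vertex
        for met_id, phi in ref.phi_wt.items():
            phi_min, phi_max = flux_sum_extrema(frozen, met_id)
            assert phi_min - 1e-6 <= phi <= phi_max + 1e-6

    def test_mixed_acid_wild_type_is_fermentative(self, mixed_acid):
        ref = reference_state(mixed_acid, "EX_succ", "maximize")
        assert ref.wt_growth == pytest.approx(15.0, abs=1e-6)
        assert ref.wt_production == pytest.approx(0.0, abs=1e-6)
        assert ref.phi_wt["pyr"] == pytest.approx(10.0, abs=1e-6)


class TestPerturbationAlgebra:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
           st.floats(0, 1))
    def test_bounds_interpolate_between_extremum_and_wild_type(
            self, k, a, b, c):
        lo, mid, hi = sorted((10 * a, 10 * b, 10 * c))
        if mid - lo < 1e-5 or hi - mid < 1e-5:
            return
        rec = FluxSumRecord("m", phi_wt=mid, phi_min=lo, phi_max=hi)
        _, att_ub = perturbation_bound(rec, ATTENUATION, k)
        int_lb, _ = perturbation_bound(rec, INTENSIFICATION, k)
        assert lo - 1e-9 <= att_ub <= mid + 1e-9
        assert mid - 1e-9 <= int_lb <= hi + 1e-9
        # k=1 attenuation and k=0 intensification are the weakest constraints
        assert perturbation_bound(rec, ATTENUATION, 1.0)[1] == pytest.approx(mid)
        assert perturbation_bound(rec, INTENSIFICATION, 0.0)[0] == pytest.approx(mid)

    def test_vacuous_ranges_are_flagged(self):
        with pytest.raises(DegenerateRangeError):
            perturbation_bound(FluxSumRecord("m", 5.0, 5.0, 9.0), ATTENUATION, 0.5)
        with pytest.raises(DegenerateRangeError):
            perturbation_bound(FluxSumRecord("m", 5.0, 0.0, 5.0),
                               INTENSIFICATION, 0.5)
        with pytest.raises(DegenerateRangeError):
            perturbation_bound(FluxSumRecord("m", 5.0, 0.0, math.inf),
                               INTENSIFICATION, 0.5)

    def test_adverse_sense_opposes_goal(self):
        assert adverse_sense("maximize") == "min"
        assert adverse_sense("minimize") == "max"


class TestPerturbationSolves:
    def test_attenuating_the_growth_feeding_node_caps_growth(self, two_branch):
        ref = reference_state(two_branch, "EX_E", "maximize")
        rec = record_for(two_branch, ref, "C")
        growth, status = growth_under_perturbation(
            two_branch, "C", ATTENUATION, 0.5, rec)
        assert status == "optimal"
        assert growth == pytest.approx(5.0, abs=1e-6)

    def test_weakest_attenuation_recovers_wild_type_growth(self, mixed_acid):
        ref = reference_state(mixed_acid, "EX_succ", "maximize")
        rec = record_for(mixed_acid, ref, "pyr")
        growth, _ = growth_under_perturbation(
            mixed_acid, "pyr", ATTENUATION, 1.0, rec)
        assert growth == pytest.approx(ref.wt_growth, abs=1e-6)

    def test_weakest_intensification_recovers_wild_type_growth(self, mixed_acid):
        ref = reference_state(mixed_acid, "EX_etoh", "maximize")
        rec = record_for(mixed_acid, ref, "acald")
        growth, _ = growth_under_perturbation(
            mixed_acid, "acald", INTENSIFICATION, 0.0, rec)
        assert growth == pytest.approx(ref.wt_growth, abs=1e-6)

    def test_displaced_flux_becomes_guaranteed_production(self, two_branch):
        ref = reference_state(two_branch, "EX_E", "maximize")
        rec = record_for(two_branch, ref, "C")
        production, status = worst_case_production(
            two_branch, "EX_E", "maximize", "C", ATTENUATION, 0.5, rec, 5.0)
        assert status == "optimal"
        assert production == pytest.approx(5.0, abs=1e-6)

    def test_minimize_goal_kills_production_at_full_attenuation(self, two_branch):
        ref = reference_state(two_branch, "EX_F", "minimize")
        rec = record_for(two_branch, ref, "C")
        growth, _ = growth_under_perturbation(
            two_branch, "C", ATTENUATION, 0.0, rec)
        assert growth == pytest.approx(0.0, abs=1e-6)
        production, _ = worst_case_production(
            two_branch, "EX_F", "minimize", "C", ATTENUATION, 0.0, rec, growth)
        assert production == pytest.approx(0.0, abs=1e-6)

    def test_worst_case_never_exceeds_best_case(self, mixed_acid):
        ref = reference_state(mixed_acid, "EX_succ", "maximize")
        rec = record_for(mixed_acid, ref, "pyr")
        for k in (0.2, 0.5, 0.8):
            growth, _ = growth_under_perturbation(
                mixed_acid, "pyr", ATTENUATION, k, rec)
            worst, _ = worst_case_production(
                mixed_acid, "EX_succ", "maximize", "pyr", ATTENUATION, k,
                rec, growth)
            best, _ = worst_case_production(
                mixed_acid, "EX_succ", "minimize", "pyr", ATTENUATION, k,
                rec, growth)  # goal=minimize flips the final sense to max
            assert worst <= best + 1e-6


class TestScan:
    def test_two_branch_minimize_f_floor_already_reached(self, two_branch):
        # The growth floor makes biomass absorb all F at every perturbation
        # level, so the guaranteed (adverse-maximum) F secretion is pinned at
        # zero everywhere and no metabolite can reduce it further.
        report = scan(two_branch, "EX_F", "minimize")
        assert report.wt_production == pytest.approx(0.0, abs=1e-6)
        assert report.targets == []
        for met, direction in (("C", ATTENUATION), ("B", INTENSIFICATION)):
            for _, _, production in production_profile(report, met, direction):
                assert production == pytest.approx(0.0, abs=1e-6)

    def test_scan_is_deterministic(self, two_branch):
        a = scan(two_branch, "EX_E", "maximize")
        b = scan(two_branch, "EX_E", "maximize")
        assert a.to_json() == b.to_json()
        assert a.points_table() == b.points_table()

    def test_profile_bookkeeping(self, two_branch, k_grid):
        report = scan(two_branch, "EX_E", "maximize")
        series = production_profile(report, "C", ATTENUATION)
        assert len(series) == len(k_grid)
        assert [k for k, _, _ in series] == sorted(k for k, _, _ in series)
        with pytest.raises(KeyError):
            production_profile(report, "A", ATTENUATION)  # degenerate, skipped

    def test_skipped_pairs_carry_reason_codes(self, two_branch):
        report = scan(two_branch, "EX_E", "maximize")
        assert ("A", ATTENUATION) in report.skipped
        assert "vacuous" in report.skipped[("A", ATTENUATION)]

    def test_exclusion_list_removes_candidates(self, two_branch):
        report = scan(two_branch, "EX_E", "maximize", exclude=("C", "F"))
        assert all(m not in ("C", "F") for m, *_ in report.targets)
        assert "C" not in report.records

    def test_report_metadata_states_conventions(self, two_branch):
        report = scan(two_branch, "EX_E", "maximize")
        md = report.metadata
        assert "lexicographic" in md["phi_wt_convention"]
        assert md["big_M"] == 1000.0
        assert md["k_grid"] == sorted(md["k_grid"])
        assert md["non_growing_wild_type"] is False

    def test_growth_monotone_along_k_for_scanned_pairs(self, two_branch):
        report = scan(two_branch, "EX_E", "maximize")
        for (met, direction) in {(p.metabolite_id, p.direction)
                                 for p in report.points}:
            series = production_profile(report, met, direction)
            growths = [g for _, g, _ in series if g is not None]
            if direction == ATTENUATION:
                assert all(b >= a - 1e-6 for a, b in zip(growths, growths[1:]))
            else:
                assert all(b <= a + 1e-6 for a, b in zip(growths, growths[1:]))
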