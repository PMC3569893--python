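"""The point-selection protocol: somatotopy, candidates, replay, simulator."""

import pytest

from meridian_balance.clock import MERIDIANS, meridian_by_code
from meridian_balance.patterns import patterns_for_meridian
from meridian_balance.protocol import (
    REGION_ZONES,
    AshiFinding,
    DeadEndError,
    PatientPresentation,
    ProtocolError,
    TreatmentStep,
    apply_step,
    candidate_meridians,
    carpenter_case,
    corresponding_regions,
    decline_affected,
    default_somatotopic_map,
    final_pattern,
    new_session,
    replay_case,
    run_scripted_case,
    select_treatment,
    simulate_cohort,
    untreated_extremities,
    zone_of,
    SimulationConfig,
)


class TestSomatotopy:
    def test_knee_correspondents(self):
        assert corresponding_regions("knee") >= {"elbow", "chest", "face_eyes", "face_nose"}

    def test_shoulder_correspondents_on_the_leg(self):
        assert corresponding_regions("shoulder") >= {"ankle", "hip", "knee"}

    def test_relation_is_symmetric(self):
        for region in REGION_ZONES:
            for other in corresponding_regions(region):
                assert region in corresponding_regions(other)

    def test_every_region_has_a_correspondent(self):
        for region in REGION_ZONES:
            assert corresponding_regions(region)

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="unknown body region"):
            corresponding_regions("tail")

    def test_user_extension(self):
        smap = default_somatotopic_map().extended([("hip", "chest", "mirror")])
        assert "chest" in smap.corresponding("hip")
        with pytest.raises(ValueError):
            default_somatotopic_map().extended([("hip", "tail", "image")])


def _si_session(side="right"):
    return new_session(
        PatientPresentation(
            affected_meridian="SI", side=side, painful_region="shoulder", vas=9
        )
    )


class TestCandidates:
    def test_yang_leg_candidates_for_affected_si(self, graph):
        state = _si_session()
        cands = candidate_meridians(state, ("leg", "either"), "yang", graph)
        assert {m.code for m in cands} == {"ST", "BL"}

    def test_yin_leg_candidates_after_bl(self, graph):
        state = _si_session()
        state = apply_step(
            state,
            TreatmentStep(meridian="BL", side="left", region="ankle"),
            5,
            graph,
        )
        cands = candidate_meridians(state, ("leg", "right"), "yin", graph)
        assert {m.code for m in cands} == {"KI", "SP"}

    def test_contralateral_arm_is_forced_yin(self, graph):
        # the arm girdle already carries yang (affected SI), so the other
        # arm must take a yin meridian even with no explicit choice
        state = _si_session()
        cands = candidate_meridians(state, ("arm", "left"), None, graph)
        assert {m.code for m in cands} == {"HT", "PC"}

    def test_conflicting_polarity_choice_rejected(self, graph):
        state = _si_session()
        with pytest.raises(ProtocolError, match="must be yin"):
            candidate_meridians(state, ("arm", "left"), "yang", graph)

    def test_affected_extremity_blocked_until_last(self, graph):
        state = _si_session()
        with pytest.raises(ProtocolError, match="affected"):
            candidate_meridians(state, ("arm", "right"), None, graph)

    def test_treated_extremity_rejected(self, graph):
        state = _si_session()
        state = apply_step(
            state, TreatmentStep(meridian="BL", side="left", region="ankle"), 5, graph
        )
        with pytest.raises(ProtocolError, match="no free leg"):
            candidate_meridians(state, ("leg", "left"), None, graph)


class TestSelection:
    def test_most_tender_finding_wins(self, graph):
        state = _si_session()
        findings = [
            AshiFinding(meridian="BL", side="left", region="ankle", tenderness=8),
            AshiFinding(meridian="ST", side="left", region="ankle", tenderness=0),
            AshiFinding(meridian="BL", side="left", region="knee", tenderness=2),
        ]
        step = select_treatment(state, findings, ("leg", "either"), "yang", graph)
        assert (step.meridian, step.region) == ("BL", "ankle")

    def test_tie_breaks_to_lower_clock_position_then_contralateral(self, graph):
        state = _si_session(side="right")
        findings = [
            AshiFinding(meridian="BL", side="left", region="ankle", tenderness=6),
            AshiFinding(meridian="ST", side="left", region="ankle", tenderness=6),
        ]
        step = select_treatment(state, findings, ("leg", "either"), "yang", graph)
        assert step.meridian == "ST"  # clock position 3 beats BL at 7

        findings = [
            AshiFinding(meridian="ST", side="right", region="ankle", tenderness=6),
            AshiFinding(meridian="ST", side="left", region="ankle", tenderness=6),
        ]
        step = select_treatment(state, findings, ("leg", "either"), "yang", graph)
        assert step.side == "left"  # contralateral to the right-sided pain

    def test_single_finding_is_chosen(self, graph):
        state = _si_session()
        findings = [AshiFinding(meridian="ST", side="left", region="knee", tenderness=1)]
        step = select_treatment(state, findings, ("leg", "either"), "yang", graph)
        assert step.meridian == "ST"

    def test_no_tender_findings_prompts_repalpation(self, graph):
        state = _si_session()
        findings = [AshiFinding(meridian="BL", side="left", region="ankle", tenderness=0)]
        with pytest.raises(ProtocolError, match="palpate other corresponding"):
            select_treatment(state, findings, ("leg", "either"), "yang", graph)

    def test_findings_outside_candidates_or_regions_rejected(self, graph):
        state = _si_session()
        with pytest.raises(ProtocolError, match="outside the candidate set"):
            select_treatment(
                state,
                [AshiFinding(meridian="KI", side="left", region="ankle", tenderness=5)],
                ("leg", "either"), "yang", graph,
            )
        with pytest.raises(ProtocolError, match="does not correspond"):
            select_treatment(
                state,
                [AshiFinding(meridian="BL", side="left", region="foot", tenderness=5)],
                ("leg", "either"), "yang", graph,
            )


class TestStateMachine:
    def test_second_meridian_on_same_extremity_rejected(self, graph):
        state = _si_session()
        state = apply_step(
            state, TreatmentStep(meridian="BL", side="left", region="ankle"), 5, graph
        )
        with pytest.raises(ProtocolError):
            apply_step(
                state, TreatmentStep(meridian="SP", side="left", region="ankle"), 4, graph
            )

    def test_full_relief_completes_early(self, graph):
        state = _si_session()
        state = apply_step(
            state, TreatmentStep(meridian="BL", side="left", region="ankle"), 0, graph
        )
        assert state.complete
        report = final_pattern(state, graph)
        assert report.partial
        assert report.members == ("SI", "BL")

    def test_affected_step_only_after_three_extremities(self, graph):
        state = _si_session()
        with pytest.raises(ProtocolError):
            apply_step(
                state, TreatmentStep(meridian="SI", side="right", region="wrist"), 5, graph
            )

    def test_decline_requires_three_treatments(self, graph):
        state = _si_session()
        with pytest.raises(ProtocolError):
            decline_affected(state)


class TestReplay:
    def test_reproduces_the_shoulder_case(self, graph):
        trace = replay_case(graph)
        assert trace.treated_sequence == ("BL", "SP", "HT", "SI")
        assert trace.vas_history == (9, 5, 3, 1, 0.5)
        assert trace.vas_history[-1] < 1
        assert [s.candidates for s in trace.stages] == [
            ("BL", "ST"), ("KI", "SP"), ("HT",), ("SI",)
        ]
        assert trace.members == ("SP", "HT", "SI", "BL")
        assert trace.pattern_class == "consecutive_window"
        assert not trace.partial

    def test_sides_follow_the_printed_decisions(self, graph):
        trace = replay_case(graph)
        assert [(s.step.meridian, s.step.side) for s in trace.stages] == [
            ("BL", "left"), ("SP", "right"), ("HT", "left"), ("SI", "right")
        ]

    def test_case_script_round_trips_through_json(self, tmp_path, graph):
        import json

        from meridian_balance.io import read_case

        script = carpenter_case()
        path = tmp_path / "case.json"
        path.write_text(json.dumps(script.model_dump(mode="json")))
        loaded = read_case(path)
        assert loaded == script
        assert run_scripted_case(loaded, graph) == run_scripted_case(script, graph)


def _walk_all_sequences(state, graph, region_for_zone):
    """Exhaust every rule-consistent choice sequence from ``state``."""
    finals = []
    if len(state.balancing_steps) == 3:
        step = TreatmentStep(
            meridian=state.affected.code,
            side=state.presentation.side,
            region=region_for_zone[state.affected_extremity[0]],
        )
        done = apply_step(state, step, 1, graph)
        finals.append(final_pattern(done, graph))
        return finals
    for target in untreated_extremities(state):
        carried = state.polarity_ledger()[target[0]]
        polarity_options = ["yin", "yang"] if not carried else [None]
        for polarity in polarity_options:
            cands = candidate_meridians(state, target, polarity, graph)
            assert cands, "protocol dead end"
            for cand in sorted(cands, key=lambda m: m.clock_position):
                step = TreatmentStep(
                    meridian=cand.code, side=target[1],
                    region=region_for_zone[target[0]],
                )
                finals.extend(
                    _walk_all_sequences(apply_step(state, step, 5, graph),
                                        graph, region_for_zone)
                )
    return finals


class TestClosure:
    def test_every_choice_sequence_lands_in_an_owned_pattern(self, graph):
        region_for_zone = {"arm": "elbow", "leg": "knee"}
        for affected in MERIDIANS:
            zone = "arm" if affected.limb == "hand" else "leg"
            state = new_session(
                PatientPresentation(
                    affected_meridian=affected.code, side="right",
                    painful_region=region_for_zone[zone], vas=7,
                )
            )
            owned = {p.members for p in patterns_for_meridian(affected, graph)}
            finals = _walk_all_sequences(state, graph, region_for_zone)
            assert finals
            for report in finals:
                assert not report.partial
                assert report.pattern is not None
                assert report.pattern.members in owned

    def test_girdle_ledger_balances_yin_and_yang(self, graph):
        region_for_zone = {"arm": "elbow", "leg": "knee"}
        state = new_session(
            PatientPresentation(
                affected_meridian="LU", side="left",
                painful_region="elbow", vas=6,
            )
        )
        for report in _walk_all_sequences(state, graph, region_for_zone):
            members = [meridian_by_code(c) for c in report.members]
            for limb in ("hand", "foot"):
                polarities = sorted(m.polarity for m in members if m.limb == limb)
                assert polarities == ["yang", "yin"]


class TestSimulator:
    def test_same_seed_gives_identical_traces(self, graph):
        a, _ = simulate_cohort(seed=11, n=15, g=graph)
        b, _ = simulate_cohort(seed=11, n=15, g=graph)
        assert [t.to_dict() for t in a] == [t.to_dict() for t in b]

    def test_different_seeds_differ(self, graph):
        a, _ = simulate_cohort(seed=1, n=15, g=graph)
        b, _ = simulate_cohort(seed=2, n=15, g=graph)
        assert [t.to_dict() for t in a] != [t.to_dict() for t in b]

    def test_complete_traces_stay_inside_the_15_patterns(self, graph, quads):
        valid = {q.member_codes for q in quads[0]}
        traces, summary = simulate_cohort(seed=5, n=60, g=graph)
        complete = [t for t in traces if not t.partial]
        assert complete
        for t in complete:
            assert tuple(t.members) == tuple(t.members) and tuple(t.members) in valid
        assert summary["partial"] + sum(
            summary["complete_patterns"].values()
        ) == summary["n"] == 60

    def test_vas_trajectories_never_increase(self, graph):
        traces, _ = simulate_cohort(seed=9, n=25, g=graph)
        for t in traces:
            assert all(b <= a for a, b in zip(t.vas_history, t.vas_history[1:]))

    def test_zero_patients_rejected(self, graph):
        with pytest.raises(ValueError, match=">= 1"):
            simulate_cohort(seed=1, n=0, g=graph)

    def test_invalid_config_rejected(self, graph):
        with pytest.raises(ValueError):
            simulate_cohort(
                seed=1, n=2, config=SimulationConfig(vas_min=8, vas_max=4), g=graph
            )
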