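"""Skill tallies, question-run measurement, conformance checking."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from mibot import (
    EngineConfig,
    MISkill,
    SimulatedUserPolicy,
    Stage,
    Transcript,
    UserTurn,
    check_conformance,
    max_consecutive_questions,
    run_session,
    tally_skills,
)
from mibot.response_generator import BotTurn


def bot(skill, stage=Stage.FOCUSING.value, tid=None, text=None, i=[0]):
    i[0] += 1
    return BotTurn(
        skill=skill,
        text=text or f"utterance {i[0]}",
        template_id=tid or f"tpl-{i[0]}",
        trigger_keyword=None,
        timestamp=float(i[0]),
        stage=stage,
        fallback=True,
    )


def transcript_of(skills, stage=Stage.FOCUSING.value):
    return Transcript(turns=[bot(s, stage) for s in skills])


class TestTallySkills:
    def test_default_responsive_session_tallies(self, reference_script, default_config):
        transcript = run_session(reference_script, default_config, SimulatedUserPolicy(seed=1))
        tallies = tally_skills(transcript)
        assert tallies[("Focusing", MISkill.FQ)] == 4
        assert tallies[("Focusing", MISkill.R)] == 4
        assert tallies[("Evoking", MISkill.EQ)] == 6
        assert tallies[("Evoking", MISkill.R)] == 6
        assert tallies[("Evoking", MISkill.MIA)] == 6
        assert sum(tallies.values()) == len(transcript.bot_turns)

    def test_empty_transcript_all_zero(self):
        assert tally_skills(Transcript(turns=[])) == {}

    def test_hand_built_transcript_counts_exactly(self):
        transcript = transcript_of([MISkill.FQ, MISkill.FQ])
        assert tally_skills(transcript) == {("Focusing", MISkill.FQ): 2}


class TestMaxConsecutiveQuestions:
    @pytest.mark.parametrize(
        "skills, expected",
        [
            ([MISkill.GI, MISkill.FQ, MISkill.R, MISkill.FQ, MISkill.FQ, MISkill.R], 2),
            ([MISkill.GI, MISkill.R, MISkill.MIA], 0),
            ([MISkill.EQ, MISkill.EQ, MISkill.EQ], 3),
            ([], 0),
        ],
    )
    def test_run_lengths(self, skills, expected):
        assert max_consecutive_questions(transcript_of(skills)) == expected

    def test_user_turns_do_not_break_a_question_run(self):
        turns = [
            bot(MISkill.FQ),
            UserTurn(text="...", timestamp=100.0, stage="Focusing"),
            bot(MISkill.FQ),
        ]
        assert max_consecutive_questions(Transcript(turns=turns)) == 2

    @given(st.lists(st.sampled_from(list(MISkill)), max_size=30))
    @settings(max_examples=200)
    def test_agrees_with_brute_force_run_scan(self, skills):
        transcript = transcript_of(skills)
        runs, run = [0], 0
        for s in skills:  # independent oracle: explicit run enumeration
            run = run + 1 if s in (MISkill.FQ, MISkill.EQ) else 0
            runs.append(run)
        assert max_consecutive_questions(transcript) == max(runs)


def engine_transcript(script, config, seed, idle=None):
    policy = SimulatedUserPolicy(seed=seed, idle_after_questions=idle)
    return run_session(script, config, policy)


class TestCheckConformance:
    @pytest.mark.parametrize("seed,idle", [(1, None), (2, 12.0), (3, None), (4, 30.0)])
    def test_engine_transcripts_are_conformant(self, reference_script, default_config, seed, idle):
        transcript = engine_transcript(reference_script, default_config, seed, idle)
        report = check_conformance(transcript, default_config)
        assert report.conformant, report.violations
        assert report.repeat_response_count == 0
        assert report.cycles == {"Focusing": 4, "Evoking": 6}
        assert report.max_consecutive_questions <= default_config.question_cap

    def test_duplicated_template_flagged_at_second_occurrence(self, reference_script, default_config):
        transcript = engine_transcript(reference_script, default_config, 5)
        turns = list(transcript.turns)
        dup_src = next(t for t in turns if isinstance(t, BotTurn) and t.stage == "Evoking")
        idx = turns.index(dup_src)
        turns[idx + 2] = dataclasses.replace(
            dup_src, timestamp=turns[idx + 2].timestamp,
            skill=turns[idx + 2].skill, stage=turns[idx + 2].stage,
        )
        report = check_conformance(Transcript(turns=turns), default_config)
        assert report.repeat_response_count >= 1
        assert any(i == idx + 2 and "repeated response template" in m for i, m in report.violations)

    def test_missing_mia_after_eq_r_pair_is_a_pattern_violation(self, reference_script, default_config):
        transcript = engine_transcript(reference_script, default_config, 6)
        turns = list(transcript.turns)
        mia_idx = next(
            i for i, t in enumerate(turns)
            if isinstance(t, BotTurn) and t.stage == "Evoking" and t.skill is MISkill.MIA
        )
        del turns[mia_idx]
        report = check_conformance(Transcript(turns=turns), default_config)
        assert not report.conformant
        assert any("Evoking" in m and "MIA" in m for _, m in report.violations)

    def test_three_questions_in_a_row_violate_the_cap(self, default_config):
        transcript = transcript_of(
            [MISkill.EQ, MISkill.EQ, MISkill.EQ], stage=Stage.EVOKING.value
        )
        report = check_conformance(transcript, default_config)
        assert report.max_consecutive_questions == 3
        assert any("consecutive questions" in m for _, m in report.violations)

    def test_non_gi_turn_in_engaging_flagged(self, default_config):
        transcript = transcript_of([MISkill.FQ], stage=Stage.ENGAGING.value)
        report = check_conformance(transcript, default_config)
        assert any("Engaging" in m for _, m in report.violations)

    def test_surplus_turns_after_final_cycle_flagged(self, reference_script, default_config):
        transcript = engine_transcript(reference_script, default_config, 7)
        turns = list(transcript.turns)
        extra = bot(MISkill.R, stage="Focusing", tid="tpl-surplus")
        last_focus = max(
            i for i, t in enumerate(turns) if isinstance(t, BotTurn) and t.stage == "Focusing"
        )
        turns.insert(last_focus + 1, extra)
        report = check_conformance(Transcript(turns=turns), default_config)
        assert any("surplus" in m for _, m in report.violations)
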