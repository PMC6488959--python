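"""Stage sequencing, cycle counting, question cap, inactivity rule."""

import pytest

from mibot import (
    ConversationState,
    EngineConfig,
    MISkill,
    Stage,
    StageConfig,
    advance,
    handle_inactivity,
    next_required_skill,
    note_user_activity,
)
from mibot.flow_manager import SessionCompleteError


def fresh(config=None, n_opening=4, n_closing=4):
    return ConversationState.initial(n_opening, n_closing)


def drive_responsive(config, n_opening=4, n_closing=4):
    """Advance through a whole session with an always-responsive user.

    Returns the list of (stage, skill) for every scheduled bot turn.
    """
    state = fresh(config, n_opening, n_closing)
    emitted = []
    t = 0.0
    while True:
        skill = next_required_skill(state, config)
        if skill is None:
            break
        emitted.append((state.stage, skill))
        advance(state, skill, config)
        t += 2.0
        note_user_activity(state, t)
    return emitted


class TestNextRequiredSkill:
    def test_fresh_state_opens_with_gi(self):
        config = EngineConfig()
        assert next_required_skill(fresh(config), config) is MISkill.GI

    def test_focusing_pattern_is_fq_then_r(self):
        config = EngineConfig()
        state = fresh(config)
        state.stage, state.cycle, state.step = Stage.FOCUSING, 0, 0
        assert next_required_skill(state, config) is MISkill.FQ
        advance(state, MISkill.FQ, config)
        assert next_required_skill(state, config) is MISkill.R

    def test_last_evoking_step_hands_over_to_planning(self):
        config = EngineConfig()
        state = fresh(config)
        state.stage, state.cycle, state.step = Stage.EVOKING, 5, 2
        assert next_required_skill(state, config) is MISkill.MIA
        advance(state, MISkill.MIA, config)
        assert state.stage is Stage.PLANNING
        assert next_required_skill(state, config) is MISkill.GI

    def test_completed_state_signals_session_end(self):
        config = EngineConfig()
        state = fresh(config)
        state.completed = True
        assert next_required_skill(state, config) is None


class TestAdvance:
    def test_default_session_emits_8_focusing_and_18_evoking_turns(self):
        emitted = drive_responsive(EngineConfig())
        assert sum(1 for st, _ in emitted if st is Stage.FOCUSING) == 8
        assert sum(1 for st, _ in emitted if st is Stage.EVOKING) == 18

    def test_single_repetition_stages_emit_pattern_lengths(self):
        config = EngineConfig(
            focusing=StageConfig(Stage.FOCUSING, (MISkill.FQ, MISkill.R), 1),
            evoking=StageConfig(Stage.EVOKING, (MISkill.EQ, MISkill.R, MISkill.MIA), 1),
        )
        emitted = drive_responsive(config)
        assert sum(1 for st, _ in emitted if st is Stage.FOCUSING) == 2
        assert sum(1 for st, _ in emitted if st is Stage.EVOKING) == 3

    def test_gi_stages_follow_template_counts(self):
        emitted = drive_responsive(EngineConfig(), n_opening=3, n_closing=2)
        assert [s for st, s in emitted if st is Stage.ENGAGING] == [MISkill.GI] * 3
        assert [s for st, s in emitted if st is Stage.PLANNING] == [MISkill.GI] * 2

    def test_advancing_completed_state_raises(self):
        config = EngineConfig()
        state = fresh(config)
        state.completed = True
        with pytest.raises(SessionCompleteError):
            advance(state, MISkill.GI, config)

    def test_question_counter_increments_and_resets(self):
        config = EngineConfig()
        state = fresh(config)
        state.stage = Stage.FOCUSING
        advance(state, MISkill.FQ, config)
        assert state.consecutive_questions == 1
        advance(state, MISkill.R, config)
        assert state.consecutive_questions == 0


class TestInactivity:
    def _waiting_after_question(self):
        config = EngineConfig()
        state = fresh(config)
        state.stage = Stage.FOCUSING
        advance(state, MISkill.FQ, config)  # counter = 1, waiting for reply
        state.last_activity = 100.0
        return config, state

    def test_idle_past_timeout_prompts_stage_appropriate_question(self):
        config, state = self._waiting_after_question()
        assert handle_inactivity(state, 111.0, config) is MISkill.FQ
        assert state.consecutive_questions == 2

    def test_cap_blocks_second_extra_question(self):
        config, state = self._waiting_after_question()
        handle_inactivity(state, 111.0, config)
        assert handle_inactivity(state, 122.0, config) is None

    def test_below_threshold_is_silent(self):
        config, state = self._waiting_after_question()
        assert handle_inactivity(state, 105.0, config) is None
        assert state.consecutive_questions == 1

    def test_rule_fires_only_while_awaiting_a_question_reply(self):
        config = EngineConfig()
        state = fresh(config)
        state.stage = Stage.FOCUSING
        advance(state, MISkill.R, config)  # counter = 0 after a reflection
        state.last_activity = 0.0
        assert handle_inactivity(state, 50.0, config) is None

    def test_rule_inactive_during_templated_gi_stages(self):
        config = EngineConfig()
        state = fresh(config)  # Engaging
        state.consecutive_questions = 1
        assert handle_inactivity(state, 50.0, config) is None

    def test_evoking_prompts_an_extra_evoking_question(self):
        config = EngineConfig()
        state = fresh(config)
        state.stage = Stage.EVOKING
        advance(state, MISkill.EQ, config)
        state.last_activity = 0.0
        assert handle_inactivity(state, 10.0, config) is MISkill.EQ


def test_patterns_with_three_adjacent_questions_rejected():
    with pytest.raises(ValueError):
        StageConfig(Stage.FOCUSING, (MISkill.FQ, MISkill.FQ, MISkill.FQ, MISkill.R), 2)


def test_config_round_trips_through_dict():
    config = EngineConfig.from_dict(
        {"focusing_reps": 2, "evoking_reps": 3, "inactivity_timeout_s": 5.0, "question_cap": 2}
    )
    assert config.to_dict() == {
        "focusing_reps": 2,
        "evoking_reps": 3,
        "inactivity_timeout_s": 5.0,
        "question_cap": 2,
    }
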