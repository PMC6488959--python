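"""Keyword matching, weighted selection, slot filling, no-repeat generation."""

import numpy as np
import pytest

from mibot import (
    ConversationState,
    MISkill,
    ResponseTemplate,
    ScriptExhaustedError,
    SlotUnresolvedError,
    extract_keywords,
    fill_template,
    generate_response,
    select_keyword,
)
from mibot.response_generator import KeywordMatch
from mibot.script_model import KeywordEntry


def fresh_state(script):
    return ConversationState.initial(len(script.gi_opening), len(script.gi_closing))


class TestExtractKeywords:
    def test_worked_example_tokens_match(self, reference_script):
        matches = extract_keywords("I don’t know if I can graduate.", reference_script)
        assert [m.entry.keyword for m in matches] == ["i", "know", "if", "i", "graduate"]
        assert [m.position for m in matches] == [0, 2, 3, 4, 6]

    def test_no_matches_for_unknown_tokens(self, reference_script):
        assert extract_keywords("zzz qqq", reference_script) == []

    def test_repeated_tokens_yield_repeated_matches(self, reference_script):
        matches = extract_keywords("know know", reference_script)
        assert [m.entry.keyword for m in matches] == ["know", "know"]


def _match(keyword, weight, position):
    return KeywordMatch(KeywordEntry(keyword, weight, {MISkill.R: ["r-0"]}), keyword, position)


class TestSelectKeyword:
    def test_highest_weight_wins_worked_example(self):
        matches = [_match("i", 1, 0), _match("know", 5, 2), _match("if", 2, 3), _match("graduate", 4, 6)]
        assert select_keyword(matches).entry.keyword == "know"

    def test_empty_input_gives_none(self):
        assert select_keyword([]) is None

    def test_weight_tie_broken_by_earliest_position(self):
        matches = [_match("later", 3, 5), _match("early", 3, 2)]
        assert select_keyword(matches).entry.keyword == "early"

    def test_agrees_with_brute_force_max_scan(self):
        rng = np.random.default_rng(42)
        keywords = [f"kw{i}" for i in range(8)]
        for _ in range(1000):
            n = int(rng.integers(1, 10))
            matches = [
                _match(keywords[int(rng.integers(0, len(keywords)))], int(rng.integers(0, 5)), pos)
                for pos in range(n)
            ]
            best = None
            for m in matches:  # independent oracle: linear scan with the tie rule
                if (
                    best is None
                    or m.entry.weight > best.entry.weight
                    or (m.entry.weight == best.entry.weight and m.position < best.position)
                    or (
                        m.entry.weight == best.entry.weight
                        and m.position == best.position
                        and m.entry.keyword < best.entry.keyword
                    )
                ):
                    best = m
            assert select_keyword(matches) == best


class TestFillTemplate:
    def test_emotion_slot_captures_phrase_after_feel(self):
        tpl = ResponseTemplate("x", MISkill.FQ, "What was helpful when you feel (client_input_emotion)?")
        out = fill_template(tpl, "These days I feel so anxious")
        assert out == "What was helpful when you feel so anxious?"

    def test_slotless_template_returned_verbatim(self):
        tpl = ResponseTemplate("x", MISkill.R, "It’s tough being a grad student.")
        assert fill_template(tpl, "whatever the user says") == "It’s tough being a grad student."

    def test_echo_slot_reflects_first_person(self):
        tpl = ResponseTemplate("x", MISkill.R, "(client_input_echo)")
        assert fill_template(tpl, "I am stuck") == "you are stuck"

    def test_topic_slot_takes_tail_after_trigger_keyword(self):
        tpl = ResponseTemplate("x", MISkill.FQ, "What does (client_input_topic) mean for you right now?")
        out = fill_template(tpl, "I keep thinking about my thesis defense", trigger_keyword="about")
        assert out == "What does your thesis defense mean for you right now?"

    def test_unresolvable_slot_raises_signal(self):
        tpl = ResponseTemplate("x", MISkill.FQ, "What was helpful when you feel (client_input_emotion)?")
        with pytest.raises(SlotUnresolvedError):
            fill_template(tpl, "no cue word here")


class TestGenerateResponse:
    def test_worked_example_emits_demo_evoking_question(self, reference_script):
        state = fresh_state(reference_script)
        turn = generate_response("I don’t know if I can graduate.", MISkill.EQ, state, reference_script)
        assert turn.skill is MISkill.EQ
        assert turn.text == "What changes do you wish to make, if any?"
        assert turn.trigger_keyword == "know"
        assert not turn.fallback

    def test_same_utterance_twice_never_repeats(self, reference_script):
        state = fresh_state(reference_script)
        first = generate_response("I don’t know if I can graduate.", MISkill.EQ, state, reference_script)
        second = generate_response("I don’t know if I can graduate.", MISkill.EQ, state, reference_script)
        assert first.template_id != second.template_id
        assert first.text != second.text

    def test_no_keyword_match_uses_fallback_pool(self, reference_script):
        state = fresh_state(reference_script)
        turn = generate_response("zzz", MISkill.R, state, reference_script)
        assert turn.fallback
        assert turn.trigger_keyword is None
        assert turn.skill is MISkill.R  # keeps the required skill for sequencing

    def test_exhausted_pools_raise_script_exhausted(self, tiny_script):
        state = fresh_state(tiny_script)
        generate_response("school", MISkill.R, state, tiny_script)   # r-000
        generate_response("school", MISkill.R, state, tiny_script)   # fallback fb-000
        with pytest.raises(ScriptExhaustedError):
            generate_response("school", MISkill.R, state, tiny_script)

    def test_gi_is_not_a_generatable_skill(self, tiny_script):
        with pytest.raises(ValueError):
            generate_response("school", MISkill.GI, fresh_state(tiny_script), tiny_script)
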