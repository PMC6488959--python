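"""ELIZA-style response generation: keyword match, template pick, slot fill.

Given a user utterance and the MI skill the flow manager requires next,
the generator tokenizes the utterance, matches tokens against the script's
weighted keyword categories, picks the highest-weighted match, and emits
the first not-yet-used response template of the required skill from that
keyword's pool.  When no keyword matches (or the pool is spent) it falls
back to the script's generic resume responses.  No rendered template is
ever reused within a conversation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .flow_manager import ConversationState
from .keyword_miner import tokenize
from .script_model import (
    PATTERN_SKILLS,
    KeywordEntry,
    MISkill,
    ResponseTemplate,
    Script,
)


class SlotUnresolvedError(Exception):
    """A filler slot could not be resolved from the utterance.

    A signal, not a crash: the caller skips the template and tries the
    next one in the pool.
    """


class ScriptExhaustedError(Exception):
    """Every applicable pool, including fallbacks, has been used up."""


@dataclass(frozen=True)
class KeywordMatch:
    """One utterance token that matched a script keyword."""

    entry: KeywordEntry
    surface: str
    position: int


@dataclass(frozen=True)
class BotTurn:
    """A single bot utterance, tagged with its MI skill and provenance.

    ``skill`` is the skill slot the turn fills in the stage sequence; a
    no-keyword-match turn keeps the required skill for sequencing but is
    tagged ``fallback=True`` and carries no trigger keyword.
    """

    skill: MISkill
    text: str
    template_id: str
    trigger_keyword: str | None
    timestamp: float
    stage: str | None = None
    fallback: bool = False


#: First-person → second-person reflection map applied token-wise.
PRONOUN_REFLECTIONS = {
    "i": "you",
    "me": "you",
    "my": "your",
    "mine": "yours",
    "am": "are",
    "myself": "yourself",
    "i'm": "you're",
    "i've": "you've",
    "i'll": "you'll",
    "i'd": "you'd",
}

_EMOTION_CUES = {"feel", "feeling", "feels", "felt"}

#: Function words stripped from the head of a topic-phrase capture.
_TOPIC_STOPWORDS = {
    "a", "an", "the", "i", "me", "to", "of", "that", "this", "it",
    "am", "is", "are", "was", "were", "can", "can't", "cannot", "could",
    "will", "would", "if", "so", "and", "but", "or", "don't", "not",
}


def reflect(tokens: list[str]) -> list[str]:
    """Flip first-person tokens to second person ("I am stuck" → "you are stuck")."""
    return [PRONOUN_REFLECTIONS.get(t, t) for t in tokens]


def extract_keywords(utterance: str, script: Script) -> list[KeywordMatch]:
    """All utterance tokens whose normalized form is a script keyword.

    One match per token occurrence, in token order; repeated tokens yield
    repeated matches.
    """
    index = script.keyword_index()
    matches = []
    for pos, token in enumerate(tokenize(utterance)):
        entry = index.get(token)
        if entry is not None:
            matches.append(KeywordMatch(entry=entry, surface=token, position=pos))
    return matches


def select_keyword(matches: list[KeywordMatch]) -> KeywordMatch | None:
    """The maximal-weight match; ties by earliest position, then keyword."""
    if not matches:
        return None
    return min(matches, key=lambda m: (-m.entry.weight, m.position, m.entry.keyword))


def _capture_slot(slot: str, tokens: list[str], trigger_keyword: str | None) -> str:
    if slot == "client_input_echo":
        captured = tokens
    elif slot == "client_input_emotion":
        captured = []
        for i, tok in enumerate(tokens):
            if tok in _EMOTION_CUES:
                captured = tokens[i + 1 :]
                break
    elif slot == "client_input_topic":
        tail = tokens
        if trigger_keyword is not None and trigger_keyword in tokens:
            tail = tokens[tokens.index(trigger_keyword) + 1 :]
        while tail and tail[0] in _TOPIC_STOPWORDS:
            tail = tail[1:]
        captured = tail
    else:
        raise SlotUnresolvedError(f"unknown slot {slot!r}")
    if not captured:
        raise SlotUnresolvedError(f"slot {slot!r} unresolvable from utterance")
    return " ".join(reflect(captured))


def fill_template(
    template: ResponseTemplate,
    utterance: str,
    trigger_keyword: str | None = None,
) -> str:
    """Render a template, replacing filler slots with reflected user input.

    Slot capture rules: ``client_input_emotion`` takes the tokens after a
    "feel"/"feeling" cue; ``client_input_topic`` takes the tail after the
    trigger keyword with leading function words stripped;
    ``client_input_echo`` reflects the whole utterance.  Captured tokens
    get first-/second-person pronoun reflection.  Slotless templates are
    returned verbatim.  Raises :class:`SlotUnresolvedError` when a slot
    cannot be resolved — the caller skips the template.
    """
    slots = template.slots
    if not slots:
        return template.text
    tokens = tokenize(utterance)
    text = template.text
    for slot in slots:
        text = text.replace(f"({slot})", _capture_slot(slot, tokens, trigger_keyword), 1)
    return text


def generate_response(
    utterance: str,
    required_skill: MISkill,
    state: ConversationState,
    script: Script,
    timestamp: float = 0.0,
    stage: str | None = None,
) -> BotTurn:
    """Produce the next bot turn for ``required_skill`` from the script.

    Walks the winning keyword's pool for the first unused, renderable
    template; falls back to the generic resume pool when no keyword
    matches or the pool is spent.  The chosen template id is recorded in
    the state ledger so no response is ever repeated in a conversation.
    Raises :class:`ScriptExhaustedError` when fallbacks too are spent.
    """
    if required_skill not in PATTERN_SKILLS:
        raise ValueError(f"required_skill must be one of {[s.value for s in PATTERN_SKILLS]}")

    best = select_keyword(extract_keywords(utterance, script))
    if best is not None:
        for tid in best.entry.pool(required_skill):
            if tid in state.used_templates:
                continue
            try:
                text = fill_template(script.template(tid), utterance, best.entry.keyword)
            except SlotUnresolvedError:
                continue
            state.used_templates.add(tid)
            return BotTurn(
                skill=required_skill,
                text=text,
                template_id=tid,
                trigger_keyword=best.entry.keyword,
                timestamp=timestamp,
                stage=stage,
            )

    for tid in script.fallbacks:
        if tid in state.used_templates:
            continue
        try:
            text = fill_template(script.template(tid), utterance)
        except SlotUnresolvedError:
            continue
        state.used_templates.add(tid)
        return BotTurn(
            skill=required_skill,
            text=text,
            template_id=tid,
            trigger_keyword=None,
            timestamp=timestamp,
            stage=stage,
            fallback=True,
        )

    raise ScriptExhaustedError(
        f"no unused template for {required_skill.value} and fallbacks are spent"
    )


__all__ = [
    "KeywordMatch",
    "BotTurn",
    "SlotUnresolvedError",
    "ScriptExhaustedError",
    "PRONOUN_REFLECTIONS",
    "reflect",
    "extract_keywords",
    "select_keyword",
    "fill_template",
    "generate_response",
]
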