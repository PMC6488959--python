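"""Run complete interview sessions: engine loop, logging, simulated users.

Ties the script, response generator and flow manager into a runnable
conversation.  The clock is injected — simulations use a
:class:`VirtualClock` so the 10-second inactivity rule is exercised
without real waiting and transcripts are bit-reproducible.  Transcripts
log to JSONL (one metadata line, then one line per turn) and round-trip
losslessly through :func:`replay_transcript`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .flow_manager import (
    ConversationState,
    EngineConfig,
    Stage,
    advance,
    handle_inactivity,
    next_required_skill,
    note_bot_turn,
    note_user_activity,
)
from .response_generator import BotTurn, ScriptExhaustedError, generate_response
from .script_model import MISkill, QUESTION_SKILLS, Script


@dataclass(frozen=True)
class UserTurn:
    text: str
    timestamp: float
    stage: str | None = None


@dataclass
class Transcript:
    """Ordered, timestamped exchange of user and bot turns plus metadata."""

    turns: list[UserTurn | BotTurn] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def bot_turns(self) -> list[BotTurn]:
        return [t for t in self.turns if isinstance(t, BotTurn)]

    @property
    def user_turns(self) -> list[UserTurn]:
        return [t for t in self.turns if isinstance(t, UserTurn)]


class VirtualClock:
    """Injected simulation clock; time moves only via :meth:`advance`."""

    def __init__(self, start: float = 0.0):
        self._t = float(start)

    def now(self) -> float:
        return self._t

    def advance(self, dt: float) -> None:
        if dt < 0:
            raise ValueError("cannot advance the clock backwards")
        self._t += dt


#: Filler tokens mixed into sampled utterances alongside script keywords.
_FILLER_TOKENS = (
    "maybe", "really", "lately", "today", "still", "just", "about",
    "always", "sometimes", "trying", "hard", "much", "very", "week",
)


@dataclass
class SimulatedUserPolicy:
    """Deterministic scripted user for tests and batch simulation.

    Replies come from a canned ``utterances`` list (cycled) or are sampled
    from ``vocabulary`` (``tokens_per_reply`` tokens per utterance).  The
    idle schedule is ``delays`` (a constant or a cycled per-turn list),
    optionally overridden by ``idle_after_questions`` whenever the last
    bot turn was a question — the knob used to provoke the inactivity
    rule.  Fully deterministic given ``seed``.
    """

    seed: int = 0
    utterances: Sequence[str] | None = None
    vocabulary: Sequence[str] | None = None
    tokens_per_reply: tuple[int, int] = (6, 12)
    delays: Sequence[float] | float = 1.0
    idle_after_questions: float | None = None

    def __post_init__(self) -> None:
        self.reset()

    def reset(self) -> None:
        """Rewind to the start of the scripted behavior (fresh RNG)."""
        self._rng = np.random.default_rng(self.seed)
        self._turn = 0

    def bind_script(self, script: Script) -> None:
        """Default the sampling vocabulary to the script's keywords."""
        if self.utterances is None and self.vocabulary is None:
            self.vocabulary = sorted(script.keyword_index()) + list(_FILLER_TOKENS)

    def next_reply(self, last_bot_turn: BotTurn) -> tuple[float, str]:
        """(delay in seconds, utterance text) for the next user turn."""
        i = self._turn
        self._turn += 1

        if isinstance(self.delays, (int, float)):
            delay = float(self.delays)
        else:
            delay = float(self.delays[i % len(self.delays)])
        if self.idle_after_questions is not None and last_bot_turn.skill in QUESTION_SKILLS:
            delay = float(self.idle_after_questions)

        if self.utterances is not None:
            text = self.utterances[i % len(self.utterances)]
        else:
            vocab = list(self.vocabulary or _FILLER_TOKENS)
            lo, hi = self.tokens_per_reply
            n = int(self._rng.integers(lo, hi + 1))
            words = [vocab[int(j)] for j in self._rng.integers(0, len(vocab), size=n)]
            text = " ".join(words).capitalize() + "."
        return delay, text


def run_session(
    script: Script,
    config: EngineConfig,
    user: SimulatedUserPolicy,
    clock: VirtualClock | None = None,
    log_path: str | Path | None = None,
) -> Transcript:
    """Execute a full Engaging → Focusing → Evoking → Planning session.

    The loop alternates bot and user turns (the summons-answer volley);
    while waiting for a slow user it consults the inactivity rule, which
    may interject one extra stage-appropriate question.  If the script
    runs out of unused responses the session closes early with the
    remaining closing GI templates and the transcript is flagged
    ``exhausted``.  Same script, config, policy and seed give a
    byte-identical transcript log.
    """
    clock = clock or VirtualClock()
    user.reset()
    user.bind_script(script)
    state = ConversationState.initial(len(script.gi_opening), len(script.gi_closing), clock.now())
    start_time = clock.now()
    turns: list[UserTurn | BotTurn] = []
    exhausted = False
    last_user_text = ""

    def emit_gi() -> BotTurn:
        ids = script.gi_opening if state.stage is Stage.ENGAGING else script.gi_closing
        tid = ids[state.gi_index]
        turn = BotTurn(
            skill=MISkill.GI,
            text=script.template(tid).text,
            template_id=tid,
            trigger_keyword=None,
            timestamp=clock.now(),
            stage=state.stage.value,
        )
        state.used_templates.add(tid)
        return turn

    def close_early() -> None:
        # Graceful close: walk the remaining closing GI templates.
        state.stage = Stage.PLANNING
        state.gi_index = 0
        state.completed = False
        while state.gi_index < state.n_closing:
            turns.append(emit_gi())
            advance(state, MISkill.GI, config)
            clock.advance(1.0)
        state.completed = True

    while True:
        skill = next_required_skill(state, config)
        if skill is None:
            break
        if skill is MISkill.GI:
            turns.append(emit_gi())
        else:
            try:
                turns.append(
                    generate_response(
                        last_user_text, skill, state, script,
                        timestamp=clock.now(), stage=state.stage.value,
                    )
                )
            except ScriptExhaustedError:
                exhausted = True
                close_early()
                break
        advance(state, skill, config)
        note_bot_turn(state, clock.now())
        if next_required_skill(state, config) is None:
            break

        delay, text = user.next_reply(turns[-1])  # type: ignore[arg-type]
        while delay >= config.inactivity_timeout:
            clock.advance(config.inactivity_timeout)
            delay -= config.inactivity_timeout
            extra_skill = handle_inactivity(state, clock.now(), config)
            if extra_skill is None:
                break
            try:
                turns.append(
                    generate_response(
                        last_user_text, extra_skill, state, script,
                        timestamp=clock.now(), stage=state.stage.value,
                    )
                )
            except ScriptExhaustedError:
                exhausted = True
                close_early()
                break
            note_bot_turn(state, clock.now())
        if exhausted:
            break
        clock.advance(delay)
        turns.append(UserTurn(text=text, timestamp=clock.now(), stage=state.stage.value))
        note_user_activity(state, clock.now())
        last_user_text = text

    transcript = Transcript(
        turns=turns,
        metadata={
            "script": script.name,
            "config": config.to_dict(),
            "seed": user.seed,
            "start_time": start_time,
            "end_time": clock.now(),
            "exhausted": exhausted,
        },
    )
    if log_path is not None:
        write_transcript(transcript, log_path)
    return transcript


class TranscriptParseError(Exception):
    """A transcript log line failed to parse; carries the line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


def _turn_to_record(turn: UserTurn | BotTurn) -> dict:
    if isinstance(turn, BotTurn):
        return {
            "type": "turn",
            "role": "bot",
            "stage": turn.stage,
            "skill": turn.skill.value,
            "text": turn.text,
            "template_id": turn.template_id,
            "trigger_keyword": turn.trigger_keyword,
            "fallback": turn.fallback,
            "t": turn.timestamp,
        }
    return {
        "type": "turn",
        "role": "user",
        "stage": turn.stage,
        "text": turn.text,
        "t": turn.timestamp,
    }


def write_transcript(transcript: Transcript, path: str | Path) -> None:
    """Write the JSONL log: a metadata line, then one line per turn."""
    lines = [json.dumps({"type": "meta", **transcript.metadata}, ensure_ascii=False, sort_keys=True)]
    lines += [
        json.dumps(_turn_to_record(t), ensure_ascii=False, sort_keys=True)
        for t in transcript.turns
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def replay_transcript(path: str | Path) -> Transcript:
    """Losslessly parse a JSONL transcript log back into a Transcript."""
    turns: list[UserTurn | BotTurn] = []
    metadata: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise TranscriptParseError(lineno, exc.msg) from exc
            kind = rec.get("type")
            if kind == "meta":
                metadata = {k: v for k, v in rec.items() if k != "type"}
            elif kind == "turn":
                try:
                    if rec["role"] == "bot":
                        turns.append(
                            BotTurn(
                                skill=MISkill(rec["skill"]),
                                text=rec["text"],
                                template_id=rec["template_id"],
                                trigger_keyword=rec["trigger_keyword"],
                                timestamp=rec["t"],
                                stage=rec["stage"],
                                fallback=rec["fallback"],
                            )
                        )
                    else:
                        turns.append(UserTurn(text=rec["text"], timestamp=rec["t"], stage=rec["stage"]))
                except (KeyError, ValueError) as exc:
                    raise TranscriptParseError(lineno, f"bad turn record: {exc}") from exc
            else:
                raise TranscriptParseError(lineno, f"unknown record type {kind!r}")
    return Transcript(turns=turns, metadata=metadata)
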