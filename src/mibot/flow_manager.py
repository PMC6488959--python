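"""Conversation flow control for the four-stage motivational interview.

The interview walks the four MI processes in order — Engaging, Focusing,
Evoking, Planning.  Engaging and Planning are templated giving-information
(GI) turns; the two middle stages repeat fixed skill patterns, by default
[FQ, R] four times in Focusing and [EQ, R, MIA] six times in Evoking,
giving 8 and 18 bot turns with an always-responsive user.  Two relational
rules are enforced here: no more than ``question_cap`` (default 2) bot
questions in a row, and a single extra stage-appropriate question is
prompted when the user stays silent past ``inactivity_timeout`` (default
10 s) after a question.

The clock is injected: every operation takes timestamps, never sleeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .script_model import MISkill, QUESTION_SKILLS


class Stage(str, Enum):
    ENGAGING = "Engaging"
    FOCUSING = "Focusing"
    EVOKING = "Evoking"
    PLANNING = "Planning"


class SessionCompleteError(Exception):
    """Raised when advancing a state whose session already finished."""


@dataclass(frozen=True)
class StageConfig:
    """Skill pattern and repetition count for one mid-conversation stage."""

    stage: Stage
    pattern: tuple[MISkill, ...]
    repetitions: int

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be positive")
        if not self.pattern:
            raise ValueError("pattern must be non-empty")
        run = 0
        for skill in self.pattern + self.pattern:  # adjacency across cycle wrap too
            run = run + 1 if skill in QUESTION_SKILLS else 0
            if run > 2:
                raise ValueError("pattern has more than 2 adjacent question skills")


@dataclass(frozen=True)
class EngineConfig:
    """Tunable engine parameters.

    ``inactivity_timeout`` is in seconds of user silence after a bot
    question before one extra question is prompted; ``question_cap``
    bounds consecutive bot questions.
    """

    focusing: StageConfig = field(
        default_factory=lambda: StageConfig(Stage.FOCUSING, (MISkill.FQ, MISkill.R), 4)
    )
    evoking: StageConfig = field(
        default_factory=lambda: StageConfig(
            Stage.EVOKING, (MISkill.EQ, MISkill.R, MISkill.MIA), 6
        )
    )
    inactivity_timeout: float = 10.0
    question_cap: int = 2

    def __post_init__(self) -> None:
        if self.inactivity_timeout <= 0:
            raise ValueError("inactivity_timeout must be positive")
        if self.question_cap < 1:
            raise ValueError("question_cap must be >= 1")

    def stage_config(self, stage: Stage) -> StageConfig:
        if stage is Stage.FOCUSING:
            return self.focusing
        if stage is Stage.EVOKING:
            return self.evoking
        raise ValueError(f"{stage.value} has no skill pattern (templated GI stage)")

    def to_dict(self) -> dict:
        return {
            "focusing_reps": self.focusing.repetitions,
            "evoking_reps": self.evoking.repetitions,
            "inactivity_timeout_s": self.inactivity_timeout,
            "question_cap": self.question_cap,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "EngineConfig":
        return cls(
            focusing=StageConfig(
                Stage.FOCUSING, (MISkill.FQ, MISkill.R), int(data.get("focusing_reps", 4))
            ),
            evoking=StageConfig(
                Stage.EVOKING,
                (MISkill.EQ, MISkill.R, MISkill.MIA),
                int(data.get("evoking_reps", 6)),
            ),
            inactivity_timeout=float(data.get("inactivity_timeout_s", 10.0)),
            question_cap=int(data.get("question_cap", 2)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "EngineConfig":
        import json

        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class ConversationState:
    """Mutable cursor over one conversation.

    Tracks the stage, the cycle/step position inside the stage pattern,
    the GI template index for the Engaging/Planning stages, the ledger of
    used template ids (the never-repeat rule), the consecutive-question
    counter, and the time of last activity for the inactivity rule.
    """

    n_opening: int
    n_closing: int
    stage: Stage = Stage.ENGAGING
    cycle: int = 0
    step: int = 0
    gi_index: int = 0
    used_templates: set[str] = field(default_factory=set)
    consecutive_questions: int = 0
    last_activity: float = 0.0
    inactivity_prompted: bool = False
    completed: bool = False

    @classmethod
    def initial(cls, n_opening: int, n_closing: int, start_time: float = 0.0) -> "ConversationState":
        if n_opening < 1 or n_closing < 1:
            raise ValueError("need at least one opening and one closing GI template")
        return cls(n_opening=n_opening, n_closing=n_closing, last_activity=start_time)


def next_required_skill(state: ConversationState, config: EngineConfig) -> MISkill | None:
    """Skill of the next scheduled bot turn, or None when the session is done.

    Engaging and Planning request GI turns in their scripted order; the
    middle stages request the current pattern position.
    """
    if state.completed:
        return None
    if state.stage in (Stage.ENGAGING, Stage.PLANNING):
        return MISkill.GI
    return config.stage_config(state.stage).pattern[state.step]


def advance(state: ConversationState, emitted_skill: MISkill, config: EngineConfig) -> ConversationState:
    """Move the cursor past one scheduled bot turn of ``emitted_skill``.

    Inactivity-inserted extra questions do not go through here — they
    consume no pattern step (see :func:`handle_inactivity`).
    """
    if state.completed:
        raise SessionCompleteError("cannot advance a completed session")

    if emitted_skill in QUESTION_SKILLS:
        state.consecutive_questions += 1
    else:
        state.consecutive_questions = 0
    state.inactivity_prompted = False

    if state.stage is Stage.ENGAGING:
        state.gi_index += 1
        if state.gi_index >= state.n_opening:
            state.stage = Stage.FOCUSING
            state.cycle = state.step = 0
    elif state.stage is Stage.PLANNING:
        state.gi_index += 1
        if state.gi_index >= state.n_closing:
            state.completed = True
    else:
        cfg = config.stage_config(state.stage)
        state.step += 1
        if state.step >= len(cfg.pattern):
            state.step = 0
            state.cycle += 1
            if state.cycle >= cfg.repetitions:
                state.cycle = 0
                if state.stage is Stage.FOCUSING:
                    state.stage = Stage.EVOKING
                else:
                    state.stage = Stage.PLANNING
                    state.gi_index = 0
    return state


def note_user_activity(state: ConversationState, now: float) -> None:
    """Record a user turn: resets the question counter and silence timer."""
    state.last_activity = now
    state.consecutive_questions = 0
    state.inactivity_prompted = False


def note_bot_turn(state: ConversationState, now: float) -> None:
    """Restart the silence window when the bot speaks."""
    state.last_activity = now


def handle_inactivity(
    state: ConversationState, now: float, config: EngineConfig
) -> MISkill | None:
    """Possibly direct one extra question after user silence.

    Fires only while the engine is waiting for the reply to a question
    (the consecutive-question counter is positive, which also confines
    the rule to the Focusing/Evoking stages), at most once per silence,
    and never beyond the question cap.  The directive is stage-appropriate
    (FQ in Focusing, EQ in Evoking) and increments the counter; it does
    not consume a pattern step.
    """
    if state.completed or state.stage not in (Stage.FOCUSING, Stage.EVOKING):
        return None
    if state.consecutive_questions == 0 or state.consecutive_questions >= config.question_cap:
        return None
    if state.inactivity_prompted:
        return None
    if now - state.last_activity < config.inactivity_timeout:
        return None
    state.consecutive_questions += 1
    state.inactivity_prompted = True
    state.last_activity = now
    return MISkill.FQ if state.stage is Stage.FOCUSING else MISkill.EQ
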