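"""Automated MI-skill coding and sequence-conformance checks on transcripts.

This is the machine-checkable slice of treatment-integrity coding: exact
per-stage behavior counts (skill tallies), the longest run of consecutive
bot questions, response-repetition detection, and verification that each
stage follows its configured skill pattern with at most one
inactivity-inserted extra question per question slot.  Question runs are
counted over bot turns only — intervening user turns do not break a run,
since the claim concerns the bot's questioning pressure.  Global relational
ratings (empathy etc.) are human judgments and are out of scope.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .flow_manager import EngineConfig, Stage, StageConfig
from .response_generator import BotTurn
from .script_model import MISkill, QUESTION_SKILLS
from .session_runtime import Transcript


class AnalysisError(Exception):
    """A transcript cannot be analyzed (e.g. an untagged bot turn)."""


@dataclass
class ConformanceReport:
    """Per-stage tallies and rule-check results over one transcript."""

    stage_tallies: dict[tuple[str, MISkill], int]
    cycles: dict[str, int]
    max_consecutive_questions: int
    repeat_response_count: int
    violations: list[tuple[int, str]] = field(default_factory=list)

    @property
    def conformant(self) -> bool:
        return not self.violations


def tally_skills(transcript: Transcript) -> dict[tuple[str, MISkill], int]:
    """Exact count of bot turns per (stage, skill)."""
    counts: Counter[tuple[str, MISkill]] = Counter()
    for i, turn in enumerate(transcript.turns):
        if isinstance(turn, BotTurn):
            if turn.skill is None:
                raise AnalysisError(f"bot turn {i} has no skill tag")
            counts[(str(turn.stage), MISkill(turn.skill))] += 1
    return dict(counts)


def max_consecutive_questions(transcript: Transcript) -> int:
    """Longest run of bot question turns (FQ/EQ) over the bot-turn sequence.

    User turns between bot questions do not break the run.
    """
    longest = run = 0
    for turn in transcript.turns:
        if not isinstance(turn, BotTurn):
            continue
        if turn.skill in QUESTION_SKILLS:
            run += 1
            longest = max(longest, run)
        else:
            run = 0
    return longest


def _scan_stage(
    indexed_skills: list[tuple[int, MISkill]],
    stage_cfg: StageConfig,
    question_cap: int,
) -> tuple[int, list[tuple[int, str]]]:
    """Match one stage's bot-skill sequence against its repeated pattern.

    Extra questions inserted by the inactivity rule appear as up to
    ``question_cap - 1`` repeats immediately after a pattern question.
    Returns (complete cycles, violations as (turn index, message)).
    """
    violations: list[tuple[int, str]] = []
    i = 0
    cycles = 0
    n = len(indexed_skills)
    while cycles < stage_cfg.repetitions:
        for expected in stage_cfg.pattern:
            if i >= n:
                last = indexed_skills[-1][0] if indexed_skills else -1
                violations.append(
                    (last, f"{stage_cfg.stage.value}: stage ended before "
                           f"{expected.value} of cycle {cycles + 1}")
                )
                return cycles, violations
            idx, got = indexed_skills[i]
            if got is not expected:
                violations.append(
                    (idx, f"{stage_cfg.stage.value}: expected {expected.value} "
                          f"in cycle {cycles + 1}, found {got.value}")
                )
                return cycles, violations
            i += 1
            if expected in QUESTION_SKILLS:
                extras = 0
                while (
                    i < n
                    and indexed_skills[i][1] is expected
                    and extras < question_cap - 1
                ):
                    extras += 1
                    i += 1
        cycles += 1
    if i < n:
        idx, got = indexed_skills[i]
        violations.append(
            (idx, f"{stage_cfg.stage.value}: {n - i} surplus turn(s) after "
                  f"cycle {cycles}, starting with {got.value}")
        )
    return cycles, violations


def check_conformance(transcript: Transcript, config: EngineConfig) -> ConformanceReport:
    """Verify stage patterns, the question cap, and response non-repetition.

    Every violation is listed with the index of the offending turn in the
    transcript.  On any engine-produced transcript the report is clean:
    zero violations, zero repeats, question runs within the cap, and
    exactly the configured number of completed cycles per stage.
    """
    violations: list[tuple[int, str]] = []
    by_stage: dict[str, list[tuple[int, MISkill]]] = {}
    for i, turn in enumerate(transcript.turns):
        if isinstance(turn, BotTurn):
            by_stage.setdefault(str(turn.stage), []).append((i, MISkill(turn.skill)))

    for stage in (Stage.ENGAGING, Stage.PLANNING):
        for idx, skill in by_stage.get(stage.value, []):
            if skill is not MISkill.GI:
                violations.append((idx, f"{stage.value}: non-GI turn {skill.value}"))

    cycles: dict[str, int] = {}
    for stage_cfg in (config.focusing, config.evoking):
        got, stage_violations = _scan_stage(
            by_stage.get(stage_cfg.stage.value, []), stage_cfg, config.question_cap
        )
        cycles[stage_cfg.stage.value] = got
        violations.extend(stage_violations)

    # Never-repeat rule: template ids and rendered texts must be unique.
    seen_id: dict[str, int] = {}
    seen_text: dict[str, int] = {}
    repeats = 0
    for i, turn in enumerate(transcript.turns):
        if not isinstance(turn, BotTurn):
            continue
        if turn.template_id in seen_id:
            repeats += 1
            violations.append(
                (i, f"repeated response template (first used at turn {seen_id[turn.template_id]})")
            )
        else:
            seen_id[turn.template_id] = i
        if turn.text in seen_text:
            violations.append(
                (i, f"repeated response text (first used at turn {seen_text[turn.text]})")
            )
        else:
            seen_text[turn.text] = i

    max_q = max_consecutive_questions(transcript)
    if max_q > config.question_cap:
        violations.append((-1, f"{max_q} consecutive questions exceed cap {config.question_cap}"))

    violations.sort()
    return ConformanceReport(
        stage_tallies=tally_skills(transcript),
        cycles=cycles,
        max_consecutive_questions=max_q,
        repeat_response_count=repeats,
        violations=violations,
    )
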