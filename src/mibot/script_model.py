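"""Chatbot script data model: keyword categories, response pools, templates.

A *script* is the complete knowledge base the engine draws on: weighted
keyword categories, per-skill response pools, opening/closing giving-
information (GI) templates, and no-match fallback responses.  Response
texts are stored once as :class:`ResponseTemplate` records; pools reference
them by id, so pool sizes counted "with repetition" are representable
without duplicating text.

The on-disk dialect is a single UTF-8 JSON file::

    {
      "metadata":  {"name": ..., "version": ...},
      "templates": [{"id": ..., "skill": ..., "text": ...}, ...],
      "categories": [{"keyword": ..., "weight": ...,
                      "responses": {"FQ": [ids...], ...}}, ...],
      "gi": {"opening": [ids...], "closing": [ids...]},
      "fallbacks": [ids...]
    }
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path


class MISkill(str, Enum):
    """Motivational-interviewing counsellor behavior codes.

    GI = giving information, FQ/EQ = focusing/evoking questions,
    R = reflection, MIA = MI-adherent statement.  FALLBACK is an
    engine-internal code for no-keyword-match responses and never
    appears in a stage pattern.
    """

    GI = "GI"
    FQ = "FQ"
    EQ = "EQ"
    R = "R"
    MIA = "MIA"
    FALLBACK = "FALLBACK"


#: Skills a mid-conversation stage pattern may request.
PATTERN_SKILLS = (MISkill.FQ, MISkill.EQ, MISkill.R, MISkill.MIA)

#: Skills that count as questions for the question cap.
QUESTION_SKILLS = frozenset({MISkill.FQ, MISkill.EQ})

#: Declared filler-slot vocabulary for response templates.
SLOT_VOCABULARY = frozenset(
    {"client_input_emotion", "client_input_topic", "client_input_echo"}
)

_SLOT_RE = re.compile(r"\((client_input_[a-z_]+)\)")


class ScriptError(Exception):
    """Base class for script-file problems."""


class ScriptFormatError(ScriptError):
    """The file does not parse as the documented script dialect."""


class ScriptValidationError(ScriptError):
    """The parsed script violates a model invariant."""

    def __init__(self, problems: list[tuple[str, str]]):
        self.problems = problems
        lines = "; ".join(f"[{sev}] {msg}" for sev, msg in problems)
        super().__init__(f"script validation failed: {lines}")


def normalize_keyword(token: str) -> str:
    """Normalize a keyword token: Unicode NFC, lowercase, ASCII apostrophe."""
    token = unicodedata.normalize("NFC", token)
    token = token.replace("’", "'").replace("‘", "'")
    return token.lower().strip()


@dataclass(frozen=True)
class ResponseTemplate:
    """A single prepared counsellor statement, possibly with filler slots.

    Slots are written ``(client_input_emotion)`` etc. in the text and are
    replaced with reflected fragments of the user's utterance at render
    time.
    """

    id: str
    skill: MISkill
    text: str

    @property
    def slots(self) -> tuple[str, ...]:
        """Names of the filler slots appearing in the text, in order."""
        return tuple(_SLOT_RE.findall(self.text))


@dataclass
class KeywordEntry:
    """A weighted keyword category with per-skill response pools.

    ``responses`` maps a skill code to the ordered list of template ids
    the engine walks when that skill is required and this keyword wins
    the weight contest.
    """

    keyword: str
    weight: int
    responses: dict[MISkill, list[str]] = field(default_factory=dict)

    def pool(self, skill: MISkill) -> list[str]:
        return self.responses.get(skill, [])


@dataclass
class Script:
    """The full chatbot script: templates, categories, GI lists, fallbacks."""

    metadata: dict = field(default_factory=dict)
    templates: dict[str, ResponseTemplate] = field(default_factory=dict)
    categories: list[KeywordEntry] = field(default_factory=list)
    gi_opening: list[str] = field(default_factory=list)
    gi_closing: list[str] = field(default_factory=list)
    fallbacks: list[str] = field(default_factory=list)

    @property
    def name(self) -> str:
        return str(self.metadata.get("name", ""))

    def keyword_index(self) -> dict[str, KeywordEntry]:
        """Mapping from normalized keyword to its category entry."""
        return {c.keyword: c for c in self.categories}

    def template(self, template_id: str) -> ResponseTemplate:
        return self.templates[template_id]


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_script`.

    ``counts`` are exact pool-slot tallies per skill, counted with
    repetition across categories; GI counts opening plus closing
    templates and FALLBACK counts the fallback list.
    """

    counts: dict[MISkill, int]
    n_categories: int
    problems: list[tuple[str, str]]

    @property
    def ok(self) -> bool:
        return not any(sev == "error" for sev, _ in self.problems)


def validate_script(script: Script) -> ValidationReport:
    """Tally pool sizes and report every invariant violation.

    Problems are reported, never raised; severity is ``"error"`` for
    invariant violations and ``"warning"`` for advisories.
    """
    problems: list[tuple[str, str]] = []

    counts: dict[MISkill, int] = {skill: 0 for skill in MISkill}
    for cat in script.categories:
        for skill, pool in cat.responses.items():
            counts[skill] += len(pool)
    counts[MISkill.GI] = len(script.gi_opening) + len(script.gi_closing)
    counts[MISkill.FALLBACK] = len(script.fallbacks)

    # Template invariants: non-empty text, declared slots, unique text per skill.
    seen_text: dict[tuple[MISkill, str], str] = {}
    for tid, tpl in script.templates.items():
        if tid != tpl.id:
            problems.append(("error", f"template registered under id {tid!r} carries id {tpl.id!r}"))
        if not tpl.text:
            problems.append(("error", f"template {tid!r} has empty text"))
        for slot in tpl.slots:
            if slot not in SLOT_VOCABULARY:
                problems.append(("error", f"template {tid!r} uses undeclared slot {slot!r}"))
        key = (tpl.skill, tpl.text)
        if key in seen_text:
            problems.append(
                ("error", f"templates {seen_text[key]!r} and {tid!r} share identical {tpl.skill.value} text")
            )
        else:
            seen_text[key] = tid

    def _check_refs(ids: list[str], where: str, expect_skill: MISkill | None) -> None:
        for tid in ids:
            tpl = script.templates.get(tid)
            if tpl is None:
                problems.append(("error", f"{where} references unknown template {tid!r}"))
            elif expect_skill is not None and tpl.skill is not expect_skill:
                problems.append(
                    ("error", f"{where} references {tid!r} of skill {tpl.skill.value}, expected {expect_skill.value}")
                )

    # Category invariants.
    if not script.categories:
        problems.append(("error", "no categories"))
    seen_kw: set[str] = set()
    for cat in script.categories:
        if cat.keyword != normalize_keyword(cat.keyword) or not cat.keyword or " " in cat.keyword:
            problems.append(("error", f"keyword {cat.keyword!r} is not a single normalized token"))
        if cat.keyword in seen_kw:
            problems.append(("error", f"duplicate keyword {cat.keyword!r}"))
        seen_kw.add(cat.keyword)
        if not isinstance(cat.weight, int) or cat.weight < 0:
            problems.append(("error", f"keyword {cat.keyword!r} has invalid weight {cat.weight!r}"))
        if not any(cat.responses.values()):
            problems.append(("error", f"keyword {cat.keyword!r} has no non-empty skill pool"))
        for skill, pool in cat.responses.items():
            if skill not in PATTERN_SKILLS:
                problems.append(
                    ("error", f"keyword {cat.keyword!r} has a pool for non-pattern skill {skill.value}")
                )
            _check_refs(pool, f"keyword {cat.keyword!r} pool {skill.value}", skill)

    if not script.gi_opening:
        problems.append(("error", "gi opening templates empty"))
    if not script.gi_closing:
        problems.append(("error", "gi closing templates empty"))
    _check_refs(script.gi_opening, "gi opening", MISkill.GI)
    _check_refs(script.gi_closing, "gi closing", MISkill.GI)
    _check_refs(script.fallbacks, "fallbacks", MISkill.FALLBACK)
    if not script.fallbacks:
        problems.append(("warning", "no fallback responses; unmatched input will exhaust the script"))

    return ValidationReport(counts=counts, n_categories=len(script.categories), problems=problems)


def _require(obj: dict, key: str, typ, where: str):
    if key not in obj:
        raise ScriptFormatError(f"{where}: missing field {key!r}")
    val = obj[key]
    if not isinstance(val, typ):
        raise ScriptFormatError(f"{where}: field {key!r} must be {typ.__name__}")
    return val


def script_from_dict(data: dict) -> Script:
    """Build a Script from the documented JSON dialect (no validation)."""
    if not isinstance(data, dict):
        raise ScriptFormatError("top level: expected an object")
    metadata = _require(data, "metadata", dict, "top level")
    templates: dict[str, ResponseTemplate] = {}
    for i, rec in enumerate(_require(data, "templates", list, "top level")):
        where = f"templates[{i}]"
        if not isinstance(rec, dict):
            raise ScriptFormatError(f"{where}: expected an object")
        tid = _require(rec, "id", str, where)
        skill_s = _require(rec, "skill", str, where)
        try:
            skill = MISkill(skill_s)
        except ValueError:
            raise ScriptFormatError(f"{where}: unknown skill {skill_s!r}") from None
        text = _require(rec, "text", str, where)
        if tid in templates:
            raise ScriptFormatError(f"{where}: duplicate template id {tid!r}")
        templates[tid] = ResponseTemplate(id=tid, skill=skill, text=text)

    categories: list[KeywordEntry] = []
    for i, rec in enumerate(_require(data, "categories", list, "top level")):
        where = f"categories[{i}]"
        if not isinstance(rec, dict):
            raise ScriptFormatError(f"{where}: expected an object")
        keyword = _require(rec, "keyword", str, where)
        weight = _require(rec, "weight", int, where)
        responses: dict[MISkill, list[str]] = {}
        for skill_s, pool in _require(rec, "responses", dict, where).items():
            try:
                skill = MISkill(skill_s)
            except ValueError:
                raise ScriptFormatError(f"{where}: unknown skill {skill_s!r}") from None
            if not isinstance(pool, list) or not all(isinstance(t, str) for t in pool):
                raise ScriptFormatError(f"{where}: pool {skill_s!r} must be a list of ids")
            responses[skill] = list(pool)
        categories.append(KeywordEntry(keyword=keyword, weight=weight, responses=responses))

    gi = _require(data, "gi", dict, "top level")
    opening = _require(gi, "opening", list, "gi")
    closing = _require(gi, "closing", list, "gi")
    fallbacks = _require(data, "fallbacks", list, "top level")
    for name, ids in (("gi.opening", opening), ("gi.closing", closing), ("fallbacks", fallbacks)):
        if not all(isinstance(t, str) for t in ids):
            raise ScriptFormatError(f"{name}: must be a list of template ids")

    return Script(
        metadata=dict(metadata),
        templates=templates,
        categories=categories,
        gi_opening=list(opening),
        gi_closing=list(closing),
        fallbacks=list(fallbacks),
    )


def script_to_dict(script: Script) -> dict:
    """Serialize a Script to the documented JSON dialect."""
    return {
        "metadata": dict(script.metadata),
        "templates": [
            {"id": t.id, "skill": t.skill.value, "text": t.text}
            for t in script.templates.values()
        ],
        "categories": [
            {
                "keyword": c.keyword,
                "weight": c.weight,
                "responses": {s.value: list(pool) for s, pool in c.responses.items()},
            }
            for c in script.categories
        ],
        "gi": {"opening": list(script.gi_opening), "closing": list(script.gi_closing)},
        "fallbacks": list(script.fallbacks),
    }


def load_script(path: str | Path) -> Script:
    """Read, parse and validate a script file.

    Raises :class:`ScriptFormatError` on parse failure (naming the
    offending field) and :class:`ScriptValidationError` listing all
    invariant violations.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ScriptFormatError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    script = script_from_dict(raw)
    report = validate_script(script)
    errors = [(s, m) for s, m in report.problems if s == "error"]
    if errors:
        raise ScriptValidationError(errors)
    return script


def save_script(script: Script, path: str | Path) -> None:
    """Write a script file; ``load_script`` of the result round-trips."""
    path = Path(path)
    payload = json.dumps(script_to_dict(script), ensure_ascii=False, indent=1, sort_keys=True)
    path.write_text(payload + "\n", encoding="utf-8")
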