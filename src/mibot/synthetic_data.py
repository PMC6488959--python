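"""Synthetic inputs: topic-labelled corpora and fixture chatbot scripts.

The real inputs behind the method were a manually topic-coded corpus of
community posts (for keyword mining) and a hand-written counselling
script.  Neither can ship here, so this module generates structured
stand-ins:

* :func:`generate_corpus` emulates the topic-coded corpus: each topic has
  a set of *planted*, topic-exclusive keywords occurring at a high rate,
  on top of a shared background vocabulary with Zipf-like frequencies —
  so planted terms have strictly maximal tf-idf in expectation and the
  mining pipeline can be validated against a known answer key.
* :func:`generate_fixture_script` builds a complete script at the
  reference scale (70 keyword categories; pool sizes FQ 209, EQ 188,
  R 166, MIA 140 counted with repetition; 8 GI templates; fallbacks),
  embedding the worked-example category set (keywords i/know/if/graduate
  with "know" maximal at weight 5, whose evoking-question pool opens with
  "What changes do you wish to make, if any?") and the published example
  response texts, so demo interactions reproduce exactly.

Both generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow_manager import EngineConfig
from .keyword_miner import Document, TopicCorpus
from .script_model import (
    KeywordEntry,
    MISkill,
    ResponseTemplate,
    Script,
)


class SpecError(ValueError):
    """A generator spec is internally inconsistent or infeasible."""


# ---------------------------------------------------------------------------
# Topic-labelled corpus
# ---------------------------------------------------------------------------

_DEFAULT_TOPICS = ("phdlife", "gradschool")

_PLANTED_BANK = (
    ("advisor", "thesis", "defense", "funding", "labwork"),
    ("coursework", "deadline", "stipend", "seminar", "roommate"),
)

_BACKGROUND_WORDS = (
    "the", "and", "to", "of", "a", "in", "that", "it", "is", "was", "for",
    "on", "with", "as", "at", "by", "be", "this", "have", "from", "or",
    "one", "had", "not", "but", "what", "all", "were", "when", "we",
    "there", "been", "has", "more", "her", "two", "like", "him", "see",
    "time", "could", "no", "make", "than", "first", "who", "my", "made",
    "over", "did", "down", "only", "way", "find", "use", "may", "water",
    "long", "little", "very", "after", "called", "just", "where", "most",
)


@dataclass
class CorpusSpec:
    """Parameters of the synthetic topic-labelled corpus.

    Defaults emulate the reference corpus scale: 2 topics with 1000
    documents each.  ``planted_rate`` is the per-document inclusion
    probability of each planted keyword; each inclusion contributes
    ``planted_occurrences`` (inclusive range) copies.  The background
    vocabulary is shared across topics and sampled with Zipf-like
    probabilities p(rank) proportional to rank**-zipf_exponent.
    """

    n_topics: int = 2
    docs_per_topic: int = 1000
    planted_per_topic: int = 5
    planted_rate: float = 0.5
    planted_occurrences: tuple[int, int] = (2, 5)
    background_vocab_size: int = 200
    background_tokens_per_doc: tuple[int, int] = (20, 40)
    zipf_exponent: float = 1.2
    seed: int = 0
    topics: tuple[str, ...] | None = None
    planted: dict[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        if self.n_topics < 1 or self.docs_per_topic < 1 or self.planted_per_topic < 1:
            raise SpecError("n_topics, docs_per_topic and planted_per_topic must be >= 1")
        if not (0 < self.planted_rate <= 1):
            raise SpecError("planted_rate must be in (0, 1]")
        if self.n_topics == 1 and self.planted_rate >= 1:
            raise SpecError(
                "with a single topic, planted_rate must be < 1 so planted terms "
                "do not occur in every document (their idf would be zero)"
            )
        if self.planted_occurrences[0] < 1 or self.planted_occurrences[0] > self.planted_occurrences[1]:
            raise SpecError("planted_occurrences must be a non-empty positive range")
        if self.topics is None:
            names = list(_DEFAULT_TOPICS[: self.n_topics])
            names += [f"topic{i:02d}" for i in range(len(names), self.n_topics)]
            self.topics = tuple(names)
        if len(self.topics) != self.n_topics:
            raise SpecError("topics must match n_topics")
        if self.planted is None:
            planted = {}
            for t, topic in enumerate(self.topics):
                bank = _PLANTED_BANK[t] if t < len(_PLANTED_BANK) else ()
                terms = list(bank[: self.planted_per_topic])
                terms += [
                    f"{topic}term{j}" for j in range(len(terms), self.planted_per_topic)
                ]
                planted[topic] = tuple(terms)
            self.planted = planted
        all_planted = [kw for terms in self.planted.values() for kw in terms]
        if len(set(all_planted)) != len(all_planted):
            raise SpecError("planted keywords must be topic-exclusive")
        if set(all_planted) & set(self._background_vocab()):
            raise SpecError("planted keywords must not occur in the background vocabulary")

    def _background_vocab(self) -> list[str]:
        vocab = list(_BACKGROUND_WORDS[: self.background_vocab_size])
        vocab += [f"word{i:03d}" for i in range(len(vocab), self.background_vocab_size)]
        return vocab


def generate_corpus(spec: CorpusSpec) -> TopicCorpus:
    """Generate the synthetic topic-labelled corpus described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    vocab = np.array(spec._background_vocab())
    ranks = np.arange(1, len(vocab) + 1, dtype=float)
    probs = ranks ** (-spec.zipf_exponent)
    probs /= probs.sum()
    lo, hi = spec.background_tokens_per_doc
    occ_lo, occ_hi = spec.planted_occurrences

    documents = []
    for topic in spec.topics or ():
        for i in range(spec.docs_per_topic):
            n_bg = int(rng.integers(lo, hi + 1))
            tokens = list(rng.choice(vocab, size=n_bg, p=probs))
            for kw in spec.planted[topic]:  # type: ignore[index]
                if rng.random() < spec.planted_rate:
                    tokens.extend([kw] * int(rng.integers(occ_lo, occ_hi + 1)))
            order = rng.permutation(len(tokens))
            text = " ".join(tokens[j] for j in order).capitalize() + "."
            documents.append(Document(doc_id=f"{topic}-{i:04d}", topic=topic, text=text))
    return TopicCorpus(documents)


# ---------------------------------------------------------------------------
# Fixture chatbot script
# ---------------------------------------------------------------------------

#: Worked-example category set: weights make "know" the uniquely maximal
#: keyword in the sentence "I don't know if I can graduate."
_DEMO_WEIGHTS = {"i": 1, "know": 5, "if": 2, "graduate": 4}
_DEMO_EQ_TEXT = "What changes do you wish to make, if any?"

#: Published example responses, seeded verbatim into the template banks.
_EXAMPLE_TEXTS: dict[MISkill, tuple[str, ...]] = {
    MISkill.FQ: (
        "In what way does this bother you?",
        "How would you feel about that?",
        "What was helpful when you feel (client_input_emotion)?",
        "What does (client_input_topic) mean for you right now?",
    ),
    MISkill.EQ: (
        _DEMO_EQ_TEXT,
        "How have you coped with difficult times in the past?",
        "What were your initial goals when you first planned for a graduate degree?",
    ),
    MISkill.R: (
        "It’s tough being a grad student.",
        "You certainly have a lot on your mind.",
    ),
    MISkill.MIA: (
        "Sometimes you show a determination that surprises even you.",
        "It seems like you are a really spirited and strong-willed person in a way.",
        "Don’t let it discourage you.",
        "That’s okay.",
    ),
}

_KEYWORD_VOCAB = (
    "advisor", "thesis", "defense", "deadline", "funding", "stipend",
    "coursework", "seminar", "lab", "experiment", "manuscript", "revision",
    "journal", "conference", "poster", "committee", "qualifier", "proposal",
    "dissertation", "fieldwork", "teaching", "grading", "tuition",
    "fellowship", "grant", "mentor", "cohort", "semester", "campus",
    "library", "dataset", "analysis", "writing", "reading", "citation",
    "review", "rejection", "publication", "research", "career", "industry",
    "academia", "postdoc", "professor", "supervisor", "burnout", "anxiety",
    "stress", "sleep", "motivation", "procrastination", "pressure",
    "workload", "balance", "family", "friends", "relationship", "health",
    "exercise", "future", "goal", "progress", "failure", "worry", "doubt",
    "confidence", "plan", "support", "lonely", "tired",
)

_TOPIC_WORDS = (
    "your thesis", "your advisor", "the deadline", "your funding",
    "the coursework", "your research", "the writing", "your committee",
    "the workload", "your progress", "the pressure", "your future",
    "the reviews", "your experiments", "the teaching load", "your sleep",
    "the uncertainty", "your motivation", "the competition", "your health",
    "the isolation", "your grades", "the stipend", "your career plans",
    "the lab work", "your work-life balance", "the qualifying exam",
    "your manuscript", "the job market", "your confidence",
)

_STEMS: dict[MISkill, tuple[str, ...]] = {
    MISkill.FQ: (
        "Can you tell me more about {w}?",
        "What about {w} concerns you the most?",
        "How does {w} affect your day-to-day life?",
        "When did {w} start to feel like a problem?",
        "What happens when you think about {w}?",
        "Who have you talked to about {w}?",
    ),
    MISkill.EQ: (
        "What would be different for you if {w} improved?",
        "How would you like things to change with {w}?",
        "What strengths could help you handle {w}?",
        "If {w} were no longer an issue, what would you do first?",
        "What small step could you take about {w} this week?",
        "What would make dealing with {w} feel worthwhile?",
    ),
    MISkill.R: (
        "It sounds like {w} weighs on you.",
        "So {w} has been taking a lot of your energy.",
        "You seem to care deeply about {w}.",
        "Dealing with {w} has not been easy for you.",
        "You are torn about {w}.",
        "Right now {w} feels bigger than everything else.",
    ),
    MISkill.MIA: (
        "The way you handle {w} shows real persistence.",
        "It takes courage to keep going despite {w}.",
        "You have already put real effort into {w}.",
        "Facing {w} the way you do says a lot about your strength.",
        "Not everyone could carry {w} as you have.",
    ),
}

_GI_OPENING = (
    "Hi, I’m here to listen. We can talk about how school has been going for you.",
    "Everything you share stays between us in this conversation.",
    "I’ll ask a few questions and reflect on what you tell me; just answer in your own words.",
    "Whenever you’re ready, let’s begin. How are you doing these days?",
)

_GI_CLOSING = (
    "We’re coming to the end of our conversation for today.",
    "Thank you for sharing so openly about your life in school.",
    "Take a moment to think over what we talked about and what it means to you.",
    "I hope some of this was helpful. Take care of yourself, and goodbye for now.",
)

_FALLBACK_TEXTS = (
    "I see. Could you tell me a little more?",
    "Go on, I’m listening.",
    "That sounds important. What else comes to mind?",
    "Mm-hmm. How does that sit with you?",
    "I hear you. What else has been on your mind?",
    "Let’s stay with that for a moment. What more can you say about it?",
    "Thanks for sharing that. What happened next?",
    "I want to understand better. Can you put it another way?",
    "That’s worth unpacking. Where would you like to start?",
    "Take your time. What feels most pressing right now?",
    "Even small details help. What else is going on?",
    "Okay. And how do you feel about all of this?",
)


@dataclass
class ScriptSpec:
    """Parameters of the fixture script generator.

    Defaults reproduce the reference script scale: 70 keyword categories,
    pool sizes (with repetition) FQ 209 / EQ 188 / R 166 / MIA 140, and
    8 GI templates split 4 opening + 4 closing.  ``distinct_fraction``
    controls how many distinct texts back each pool; the remaining slots
    are repeated references across categories.
    """

    n_categories: int = 70
    pool_sizes: dict[MISkill, int] = field(
        default_factory=lambda: {MISkill.FQ: 209, MISkill.EQ: 188, MISkill.R: 166, MISkill.MIA: 140}
    )
    n_gi_opening: int = 4
    n_gi_closing: int = 4
    n_fallbacks: int = 12
    weight_range: tuple[int, int] = (1, 5)
    distinct_fraction: float = 0.62
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_categories < 1:
            raise SpecError("n_categories must be >= 1")
        for skill in (MISkill.FQ, MISkill.EQ, MISkill.R, MISkill.MIA):
            if self.pool_sizes.get(skill, 0) < 1:
                raise SpecError(f"pool size for {skill.value} must be >= 1")
        if self.n_gi_opening < 1 or self.n_gi_closing < 1:
            raise SpecError("need at least one opening and one closing GI template")
        if self.n_fallbacks < 0:
            raise SpecError("n_fallbacks must be >= 0")
        if not (0 < self.distinct_fraction <= 1):
            raise SpecError("distinct_fraction must be in (0, 1]")
        lo, hi = self.weight_range
        if lo < 0 or lo > hi:
            raise SpecError("weight_range must be a non-empty non-negative range")


def session_capacity_problems(script: Script, config: EngineConfig) -> list[str]:
    """Why ``script`` could fail to carry one full session under ``config``.

    A full default session needs, per skill, at least as many distinct
    templates as the stage patterns can demand — question slots count up
    to ``question_cap`` times for inactivity headroom.
    """
    from .script_model import QUESTION_SKILLS

    needs: dict[MISkill, int] = {}
    for stage_cfg in (config.focusing, config.evoking):
        for skill in stage_cfg.pattern:
            per_cycle = config.question_cap if skill in QUESTION_SKILLS else 1
            needs[skill] = needs.get(skill, 0) + per_cycle * stage_cfg.repetitions
    distinct: dict[MISkill, set[str]] = {}
    for cat in script.categories:
        for skill, pool in cat.responses.items():
            distinct.setdefault(skill, set()).update(pool)
    problems = [
        f"{skill.value}: {len(distinct.get(skill, set()))} distinct templates < "
        f"{need} potentially needed for a full session"
        for skill, need in needs.items()
        if len(distinct.get(skill, set())) < need
    ]
    if not script.fallbacks:
        problems.append("no fallback responses for no-match turns")
    return problems


def _template_bank(skill: MISkill, n: int) -> list[str]:
    """``n`` distinct response texts for a skill, examples first."""
    texts: list[str] = []
    seen: set[str] = set()
    for text in _EXAMPLE_TEXTS[skill]:
        if text not in seen:
            texts.append(text)
            seen.add(text)
    for stem in _STEMS[skill]:
        for w in _TOPIC_WORDS:
            text = stem.format(w=w)
            if text not in seen:
                texts.append(text)
                seen.add(text)
            if len(texts) >= n:
                return texts[:n]
    k = 0
    while len(texts) < n:  # numbered overflow beyond the phrase bank
        text = f"{_STEMS[skill][0].format(w=_TOPIC_WORDS[0])[:-1]} (take {k})?"
        if text not in seen:
            texts.append(text)
            seen.add(text)
        k += 1
    return texts[:n]


def generate_fixture_script(
    spec: ScriptSpec,
    ensure_session: EngineConfig | None = None,
) -> Script:
    """Build a fixture script to ``spec``; deterministic given the seed.

    Validator tallies equal the spec's pool sizes exactly.  When
    ``ensure_session`` is given, the script is checked to hold enough
    distinct material for one full session under that configuration and a
    :class:`SpecError` is raised otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    templates: dict[str, ResponseTemplate] = {}

    def add(skill: MISkill, text: str, prefix: str, idx: int) -> str:
        tid = f"{prefix}-{idx:03d}"
        templates[tid] = ResponseTemplate(id=tid, skill=skill, text=text)
        return tid

    gi_opening = [add(MISkill.GI, t, "gi-open", i) for i, t in enumerate(_GI_OPENING[: spec.n_gi_opening])]
    while len(gi_opening) < spec.n_gi_opening:
        i = len(gi_opening)
        gi_opening.append(add(MISkill.GI, f"Let me add one more thought before we start (note {i}).", "gi-open", i))
    gi_closing = [add(MISkill.GI, t, "gi-close", i) for i, t in enumerate(_GI_CLOSING[: spec.n_gi_closing])]
    while len(gi_closing) < spec.n_gi_closing:
        i = len(gi_closing)
        gi_closing.append(add(MISkill.GI, f"One last thing before we finish (note {i}).", "gi-close", i))
    fallbacks = [
        add(MISkill.FALLBACK, _FALLBACK_TEXTS[i % len(_FALLBACK_TEXTS)]
            if i < len(_FALLBACK_TEXTS)
            else f"I’m still with you. What else would you like to add? (nudge {i})",
            "fb", i)
        for i in range(spec.n_fallbacks)
    ]

    skills = (MISkill.FQ, MISkill.EQ, MISkill.R, MISkill.MIA)
    banks: dict[MISkill, list[str]] = {}
    for skill in skills:
        slots = spec.pool_sizes[skill]
        # Bank must cover the largest per-category pool so slot totals stay
        # exact while pools remain within-category distinct.
        per_cat = -(-slots // spec.n_categories) + 1
        n_distinct = max(1, min(slots, max(int(np.ceil(spec.distinct_fraction * slots)), per_cat)))
        texts = _template_bank(skill, n_distinct)
        banks[skill] = [add(skill, t, skill.value.lower(), i) for i, t in enumerate(texts)]

    # Keyword list: worked-example categories first, then domain vocabulary.
    demo_keywords = list(_DEMO_WEIGHTS)
    extra = [w for w in _KEYWORD_VOCAB if w not in _DEMO_WEIGHTS]
    n_extra = spec.n_categories - len(demo_keywords)
    if n_extra < 0:
        demo_keywords = demo_keywords[: spec.n_categories]
        n_extra = 0
    keywords = demo_keywords + extra[:n_extra]
    k = 0
    while len(keywords) < spec.n_categories:  # overflow beyond the vocabulary
        kw = f"keyword{k:02d}"
        if kw not in keywords:
            keywords.append(kw)
        k += 1

    lo, hi = spec.weight_range
    categories: list[KeywordEntry] = []
    for kw in keywords:
        weight = _DEMO_WEIGHTS.get(kw, int(rng.integers(lo, hi + 1)))
        categories.append(KeywordEntry(keyword=kw, weight=weight, responses={}))

    # Distribute pool slots over categories and assign rotating references:
    # consecutive bank templates per category, wrapping around, so slot
    # totals are exact, every pool is within-category distinct, and texts
    # repeat across categories once the bank is shorter than the slots.
    for skill in skills:
        slots = spec.pool_sizes[skill]
        bank = banks[skill]
        base, rem = divmod(slots, spec.n_categories)
        cursor = 0
        for ci, cat in enumerate(categories):
            k_slots = base + (1 if ci < rem else 0)
            refs = [bank[(cursor + j) % len(bank)] for j in range(k_slots)]
            cursor += k_slots
            if refs:
                cat.responses[skill] = refs

    # Pin the demo evoking question to the head of the "know" pool so the
    # worked example renders from a fresh conversation state.
    demo_eq_id = next(
        tid for tid, t in templates.items()
        if t.skill is MISkill.EQ and t.text == _DEMO_EQ_TEXT
    )
    for cat in categories:
        if cat.keyword == "know" and cat.responses.get(MISkill.EQ):
            refs = cat.responses[MISkill.EQ]
            rest = [r for r in refs if r != demo_eq_id]
            cat.responses[MISkill.EQ] = ([demo_eq_id] + rest)[: len(refs)]

    script = Script(
        metadata={
            "name": "synthetic-fixture",
            "version": "1",
            "seed": spec.seed,
            "synthetic": True,
        },
        templates=templates,
        categories=categories,
        gi_opening=gi_opening,
        gi_closing=gi_closing,
        fallbacks=fallbacks,
    )
    if ensure_session is not None:
        problems = session_capacity_problems(script, ensure_session)
        if problems:
            raise SpecError("script too small for a full session: " + "; ".join(problems))
    return script
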