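"""Weighted-keyword mining from a topic-labelled corpus via tf-idf.

The original script's keywords came from a manually topic-coded corpus of
community posts: a per-topic tf-idf ranking surfaced candidate keywords,
and domain-relevant ones were then boosted to higher weights.  This module
reproduces that pipeline with an explicit, reproducible convention:

* tf(t, c)  = total occurrences of term *t* in documents of topic *c*
* idf(t)    = ln(N / df(t)), N = corpus size, df = documents containing *t*
  (no smoothing; terms occurring in every document score exactly 0 and
  drop out, which removes stopword-like terms automatically)
* score     = tf · idf

Per topic, the ``top_k`` terms by score become keywords; the base weight is
the rank quantile mapped onto ``1..base_weight_levels`` (best rank gets the
top level), and boost rules add integer bonuses so domain terms outrank
generic ones.  All ties break lexicographically for determinism.
"""

from __future__ import annotations

import math
import re
import unicodedata
import warnings
from collections import Counter
from dataclasses import dataclass, field

from .script_model import KeywordEntry, normalize_keyword

_TOKEN_RE = re.compile(r"[^\W_]+(?:'[^\W_]+)*")


@dataclass(frozen=True)
class Document:
    doc_id: str
    topic: str
    text: str


@dataclass
class TopicCorpus:
    """A corpus of topic-labelled documents (one text per record)."""

    documents: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        for doc in self.documents:
            if not doc.topic:
                raise ValueError(f"document {doc.doc_id!r} has an empty topic label")

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def topics(self) -> list[str]:
        """Distinct topic labels in first-seen order."""
        seen: dict[str, None] = {}
        for doc in self.documents:
            seen.setdefault(doc.topic, None)
        return list(seen)

    @classmethod
    def from_records(cls, records) -> "TopicCorpus":
        """Build from an iterable of (doc_id, topic, text) triples or dicts."""
        docs = []
        for rec in records:
            if isinstance(rec, dict):
                docs.append(Document(str(rec["doc_id"]), str(rec["topic"]), str(rec["text"])))
            else:
                doc_id, topic, text = rec
                docs.append(Document(str(doc_id), str(topic), str(text)))
        return cls(docs)


@dataclass(frozen=True)
class TermScore:
    """tf-idf score of one term within one topic."""

    term: str
    topic: str
    tf: int
    df: int
    score: float


@dataclass(frozen=True)
class BoostRule:
    """Additive weight bonus for a set of terms.

    Boosted terms are also whitelisted: they stay in the candidate ranking
    even when their idf is zero (term present in every document).
    """

    terms: frozenset[str]
    bonus: int

    def __post_init__(self) -> None:
        if self.bonus < 0:
            raise ValueError("boost bonus must be non-negative")
        object.__setattr__(self, "terms", frozenset(normalize_keyword(t) for t in self.terms))


def tokenize(text: str) -> list[str]:
    """Split free text into normalized tokens.

    Lowercase; punctuation stripped except intra-word apostrophes, so
    contractions stay whole ("don't" stays one token).  Curly apostrophes
    are mapped to ASCII.  Deterministic; empty text gives an empty list.
    """
    text = unicodedata.normalize("NFC", text)
    text = text.replace("’", "'").replace("‘", "'")
    return _TOKEN_RE.findall(text.lower())


def tfidf_scores(corpus: TopicCorpus) -> list[TermScore]:
    """Score every (term, topic) pair; sorted by topic, -score, term."""
    if len(corpus) == 0:
        raise ValueError("cannot score an empty corpus")
    n_docs = len(corpus)
    df: Counter[str] = Counter()
    tf_by_topic: dict[str, Counter[str]] = {}
    for doc in corpus.documents:
        tokens = tokenize(doc.text)
        df.update(set(tokens))
        tf_by_topic.setdefault(doc.topic, Counter()).update(tokens)

    topic_order = {t: i for i, t in enumerate(corpus.topics)}
    scores = [
        TermScore(
            term=term,
            topic=topic,
            tf=tf,
            df=df[term],
            score=tf * math.log(n_docs / df[term]),
        )
        for topic, counts in tf_by_topic.items()
        for term, tf in counts.items()
    ]
    scores.sort(key=lambda s: (topic_order[s.topic], -s.score, s.term))
    return scores


def derive_keywords(
    corpus: TopicCorpus,
    top_k: int,
    boosts: list[BoostRule] | None = None,
    base_weight_levels: int = 5,
) -> list[KeywordEntry]:
    """Mine weighted keyword categories from a topic-labelled corpus.

    Per topic the ``top_k`` highest-scoring terms are kept (zero-score
    stopword-like terms are dropped unless a boost rule whitelists them)
    and given base weights from the rank quantile on ``1..levels``; boost
    bonuses are added, and a keyword surfacing in several topics keeps its
    maximum weight.  Returned entries carry empty response pools — pools
    are attached when a script is assembled around the keywords.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if base_weight_levels < 1:
        raise ValueError("base_weight_levels must be >= 1")
    boosts = boosts or []
    bonus: dict[str, int] = {}
    for rule in boosts:
        for term in rule.terms:
            bonus[term] = bonus.get(term, 0) + rule.bonus

    by_topic: dict[str, list[TermScore]] = {}
    for ts in tfidf_scores(corpus):
        by_topic.setdefault(ts.topic, []).append(ts)

    weights: dict[str, int] = {}
    for topic in corpus.topics:
        candidates = [ts for ts in by_topic.get(topic, []) if ts.score > 0 or ts.term in bonus]
        if len(candidates) < top_k:
            warnings.warn(
                f"topic {topic!r}: only {len(candidates)} candidate terms for top_k={top_k}",
                stacklevel=2,
            )
        taken = candidates[:top_k]  # already sorted by (-score, term)
        m = len(taken)
        for rank, ts in enumerate(taken):
            base = base_weight_levels - (rank * base_weight_levels) // m
            weight = base + bonus.get(ts.term, 0)
            weights[ts.term] = max(weights.get(ts.term, 0), weight)

    return [
        KeywordEntry(keyword=term, weight=weights[term], responses={})
        for term in sorted(weights)
    ]
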