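# Methods

## The conversation model

The engine delivers a brief motivational interview as a deterministic
state machine over the four MI processes. Engaging and Planning are
templated giving-information (GI) turns taken in scripted order from the
opening and closing lists. Focusing repeats the skill pattern `[FQ, R]`
and Evoking repeats `[EQ, R, MIA]`; with the default repetition counts
(4 and 6) a fully responsive session contains exactly 8 Focusing and 18
Evoking bot turns. The interaction is a summons–answer volley: after every
bot turn except the last, the engine waits for one user turn.

Two relational constraints are modelled explicitly:

- **Question cap.** A consecutive-question counter increments on each bot
  FQ/EQ and resets on any non-question bot turn or user reply; it may
  never exceed `question_cap` (default 2). Question runs are *counted over
  bot turns only* — an intervening user turn does not break a run, because
  the constraint concerns the bot's questioning pressure, not turn
  adjacency. For that reason the inactivity rule (below) fires only while
  the engine is waiting for the reply to a question (counter > 0): if it
  could fire after a reflection, an extra question, the next pattern
  question and a second extra question would form a 3-question bot run
  even though user turns sat between them.
- **Inactivity rule.** If the user is silent for `inactivity_timeout`
  seconds (default 10) after a question, the engine prompts one extra
  stage-appropriate question (FQ in Focusing, EQ in Evoking). The extra
  question consumes no pattern step, fires at most once per silence, and
  respects the question cap, so each question slot emits one or two
  questions and stage turn totals are 8/18 "plus possible extras". The
  rule is inert in the GI stages.

The clock is an injected dependency (`VirtualClock` in simulation, the
monotonic clock in interactive chat), so the time rule is testable without
sleeping and simulated transcripts are byte-reproducible.

## Response generation

Non-GI turns are produced ELIZA-style from a prepared script. Tokenization
lowercases, strips punctuation but keeps intra-word apostrophes
("don't" stays whole), and maps curly apostrophes to ASCII. Every token
matching a keyword category produces a match; the highest-weighted keyword
wins, ties broken by earliest position and then lexicographically. The
turn takes the first *unused* template of the required skill from the
winning keyword's pool; if no keyword matched or the pool is spent, the
first unused fallback is used instead (tagged `fallback`, keeping the
required skill for sequencing so the pattern cursor still advances). A
global used-template ledger enforces the never-repeat rule; when even the
fallbacks are spent the session closes early with the remaining closing GI
templates and the transcript is flagged `exhausted`.

Filler slots use a small capture grammar, since only the slot concept —
not a grammar — is given in the source material: `client_input_emotion`
takes the tokens after a "feel/feeling/felt" cue; `client_input_topic`
takes the tail after the trigger keyword with leading function words
stripped; `client_input_echo` takes the whole utterance. Captured tokens
get first-to-second-person pronoun reflection (I→you, my→your, am→are,
…). An unresolvable slot makes the caller skip that template rather than
emit garbled text.

## Keyword mining

Keyword weights are derived from a topic-labelled corpus with an explicit
tf-idf convention: `tf(t, c)` is the total count of term *t* in topic *c*,
`idf(t) = ln(N / df(t))` with no smoothing, and `score = tf · idf`. Terms
in every document score exactly 0 and drop out, which removes stopwords
without a stopword list. Per topic the `top_k` terms become keywords; base
weights map the rank quantile onto 1..5 (the observed weight scale of the
original script), boost rules add integer bonuses so domain-relevant terms
rank higher, and a keyword surfacing in several topics keeps its maximum
weight. All ties break lexicographically, so mining is fully
deterministic. scikit-learn's vectorizers are deliberately not used: their
smoothed, per-document idf differs from this stated convention.

## Synthetic data

Two generators stand in for inputs that cannot ship:

- **Corpus.** Emulates a manually topic-coded community-post corpus:
  2 topics × 1000 documents by default. Each document carries 20–40
  background tokens drawn from a 200-word shared vocabulary with Zipf-like
  probabilities (exponent 1.2), and each of the topic's 5 planted,
  topic-exclusive keywords is included with probability 0.5, contributing
  2–5 occurrences. These rates make a planted term's expected tf-idf
  several times larger than any background term's even in the single-topic
  case (where planted idf is only `ln(1/rate)`), which is what makes the
  planted-recovery property hold across seeds. What the generator does
  *not* emulate: real linguistic structure, topic overlap, misspellings,
  or document-length/topic correlations — so passing recovery tests shows
  the pipeline is correct, not that it would mine good keywords from real
  community text.
- **Fixture script.** Reproduces the reference script's scale: 70 keyword
  categories; pool sizes, counted with repetition, of 209 FQ, 188 EQ,
  166 R and 140 MIA; 8 GI templates (split 4 opening + 4 closing); and 12
  fallbacks (the original count is not reported; 12 leaves headroom so a
  default session cannot run out of responses, which a property test
  checks). Distinct template texts number about 62% of the pool slots;
  pools reference texts by id, repeating across categories, which is how
  "pool size with repetition" exceeds the count of distinct statements.
  The worked-example category set (keywords `i`/`know`/`if`/`graduate`
  with weights 1/5/2/4 and the evoking question "What changes do you wish
  to make, if any?" at the head of `know`'s pool) and the published
  example response texts are embedded verbatim so demo interactions
  reproduce exactly. Other keywords come from a graduate-school
  vocabulary; other texts are generated counselling-style sentences.

## Conformance analytics

`check_conformance` verifies, over the bot-skill sequence of each stage,
the regular pattern `(FQ R | FQ FQ R)^4` in Focusing and
`(EQ R MIA | EQ EQ R MIA)^6` in Evoking (generalized to the configured
pattern, with up to `question_cap` adjacent copies of each question slot),
counts completed cycles, measures the maximum consecutive-question run,
and detects repeated template ids or response texts. Violations carry the
index of the offending turn. Only behavior counts are automated; global
relational ratings (e.g. empathy) are human judgments and out of scope.

## Numerical and design choices

- Keyword normalization: Unicode NFC, lowercase, ASCII apostrophes.
- Pool traversal is the script's list order (no randomness), so response
  choice is reproducible; weights are small integers, and all orderings
  break ties deterministically.
- Engine defaults: `focusing_reps=4`, `evoking_reps=6`,
  `inactivity_timeout_s=10`, `question_cap=2`.
- Simulated-user replies are sampled from the script's keyword vocabulary
  plus filler words (6–12 tokens per reply), so most turns have keyword
  matches, as with real users of a domain-targeted script; delays come
  from a cycled schedule or an `idle_after_questions` override.
- Problem sizes in the acceptance script: one responsive session for the
  turn/cycle counts (they are deterministic given the state machine) and
  100 idle-scheduled sessions for the question-cap bound.
- Fallback turns keep the required skill tag; a transcript dominated by
  fallbacks still sequences correctly but carries less MI content — the
  `fallback` flag makes this auditable.

## Known limitations

- The engine is a script player: it cannot leave the fixed sequence,
  branch on topics, or detect sentiment; fidelity to MI's relational
  spirit beyond the modelled rules (question pacing, no repetition,
  contextualized statements) is not measured.
- Slot capture is heuristic and English-only; reflected fragments can be
  ungrammatical for complex clauses.
- Synthetic fixtures validate mechanics, not counselling quality; no
  claim about user-perceived empathy or stress outcomes follows from
  these tests.
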