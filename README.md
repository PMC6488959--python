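# mibot

A rule-based conversational agent that delivers a **brief motivational
interview** (MI) as a fixed four-stage sequence of counsellor skills, plus
the tooling around it: tf-idf keyword mining from topic-labelled corpora,
a deterministic session runtime with simulated users, and automated
transcript conformance analytics.

It is aimed at researchers in digital mental health and conversational
systems who want a fully scripted, auditable MI interaction — every
response is a prepared counsellor statement, every skill choice follows a
declared state machine, and every conversation can be replayed and checked
against the design.

## The model

Motivational interviewing structures a counselling conversation as four
processes — *Engaging, Focusing, Evoking, Planning* — realized through
counsellor behavior codes: **GI** (giving information), **FQ**/**EQ**
(focusing/evoking questions), **R** (reflections), and **MIA**
(MI-adherent affirmations). The engine walks the stages as a summons–answer
volley (*abab*): the bot speaks, the user answers, the bot responds in the
next scheduled skill.

- **Engaging / Planning**: templated GI turns from the script's opening
  and closing lists (4 + 4 by default).
- **Focusing**: the pattern `[FQ, R]` repeated **4** times → 8 bot turns.
- **Evoking**: the pattern `[EQ, R, MIA]` repeated **6** times → 18 bot turns.
- **Relational rules**: never more than **2** questions in a row; if the
  user is silent for **10 s** after a question, one extra stage-appropriate
  question is prompted; no response is ever repeated within a session.

Each non-GI turn is generated ELIZA-style: the utterance is tokenized,
tokens are matched against weighted keyword categories, the
highest-weighted keyword *k* wins (ties: earliest position, then
lexicographic), and the first unused template of the required skill in
*k*'s pool is rendered, with filler slots replaced by pronoun-reflected
fragments of the user's input. Keyword weights come from per-topic tf-idf
over a labelled corpus — `score(t, c) = tf(t, c) · ln(N / df(t))` — mapped
to integer weights 1..5 by rank, plus additive domain boosts.

## Worked example

```python
from mibot import (ConversationState, EngineConfig, MISkill, ScriptSpec,
                   SimulatedUserPolicy, generate_fixture_script,
                   generate_response, run_session, tally_skills)

script = generate_fixture_script(ScriptSpec(seed=0))   # 70 categories, full pools
state = ConversationState.initial(4, 4)
turn = generate_response("I don't know if I can graduate.", MISkill.EQ, state, script)
print(turn.trigger_keyword, turn.text)
```

prints

```
know What changes do you wish to make, if any?
```

The tokens `i`, `know`, `if`, `graduate` all match keyword categories, with
weights 1, 5, 2 and 4; `know` wins at weight 5, and the first unused
evoking question in its pool is emitted. A full simulated session:

```python
transcript = run_session(script, EngineConfig(), SimulatedUserPolicy(seed=1))
print(tally_skills(transcript))
```

```
{('Engaging', <MISkill.GI: 'GI'>): 4, ('Focusing', <MISkill.FQ: 'FQ'>): 4,
 ('Focusing', <MISkill.R: 'R'>): 4, ('Evoking', <MISkill.EQ: 'EQ'>): 6,
 ('Evoking', <MISkill.R: 'R'>): 6, ('Evoking', <MISkill.MIA: 'MIA'>): 6,
 ('Planning', <MISkill.GI: 'GI'>): 4}
```

i.e. 8 Focusing and 18 Evoking bot turns, 4 FQ-R and 6 EQ-R-MIA cycles.

## Command line

```bash
mibot fixtures script --reference-scale --seed 0 --out script.json
mibot validate script.json                      # pool tallies + problems
mibot fixtures corpus --seed 0 --out corpus.jsonl
mibot mine --corpus corpus.jsonl --top-k 5 --out keywords.json
mibot simulate --script script.json --seed 2 --log session.jsonl
mibot analyze --log session.jsonl               # conformance report
mibot chat --script script.json                 # interactive, real clock
```

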