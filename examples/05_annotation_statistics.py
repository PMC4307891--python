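"""Record per-instance correctness votes and summarize annotation quality.

Annotators judge whether a relation was correctly extracted from a given
sentence.  The summaries answer: what fraction of votes were "correct",
how instances class up (always correct, majority correct, tied), and how
often co-annotators agree (the unanimity ratio).
"""

from predqa import (
    SynthConfig,
    agreement,
    generate_synthetic_store,
    generate_synthetic_votes,
    instance_summary,
    vote_summary,
)

store = generate_synthetic_store(SynthConfig(seed=42))
log = generate_synthetic_votes(store, seed=44, n_users=12, p_correct=0.68)

vs = vote_summary(log)
print(f"{vs.n_votes_decided} decided votes: {vs.n_correct} correct "
      f"({vs.pct_correct}%), {vs.n_wrong} wrong ({vs.pct_wrong}%), "
      f"{vs.n_undecided} undecided (excluded from percentages)")

s = instance_summary(log)
print(f"{s.n_instances} instances: {s.always_correct} always correct "
      f"({s.pct_always_correct}%), {s.more_correct_than_wrong} majority-correct "
      f"({s.pct_more_correct_than_wrong}%), {s.tied} tied ({s.pct_tied}%)")

s2 = instance_summary(log, "at_least", 2)
print(f"restricted to >=2 evaluators: {s2.n_instances} instances, "
      f"{s2.pct_more_correct_than_wrong}% majority-correct")

for k in (2, 3):
    ratio = agreement(log, k)
    shown = "n/a" if ratio is None else f"{ratio:.2f}"
    print(f"unanimity among exactly-{k}-evaluator instances: {shown}")
# The unanimity ratio is the simple agreement measure: unanimous / total.
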