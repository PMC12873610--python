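# quorum

Agreement-threshold consensus over multi-rater panels for evidence synthesis.

Systematic reviews and meta-research spend enormous human effort on two
repetitive tasks: screening abstracts (e.g. classifying a randomized trial's
intervention as *drug* vs *nondrug*) and extracting simple facts from them
(e.g. the number of randomized patients, or *missing* when the abstract does
not report it). Individual language models do these tasks with uneven,
model-dependent accuracy — not reliably enough to replace a human reviewer.
`quorum` implements the selective-prediction remedy: ask a **panel of N
raters** and accept an answer only when at least **T of them give the
identical response**; otherwise the item is *withheld* and left for human
review. Because independently trained raters tend to make *different*
mistakes, disagreement is a strong signal of unreliability, and the accepted
subset can be far more accurate than any single rater — at the cost of
deciding fewer items. The (N, T) pair is the whole tuning surface.

The package provides, for people running or studying such pipelines:

- **`quorum.core`** — the decision rule itself: exact-match tallies over
  valid responses (unparseable "format issue" responses occupy a panel slot
  but support nothing), a unique-winner-at-threshold criterion, abstention
  otherwise.
- **`quorum.sweep`** — exhaustive evaluation of every rater subset of each
  panel size at every threshold from strict majority to unanimity, with
  median/IQR summaries per (N, T): the accuracy–coverage frontier.
- **`quorum.metrics`** — accuracy on decided items, accuracy over all items
  (tied by `overall = decided × coverage`), coverage, per-class
  precision/recall/F1, and subgroup-stratified reports.
- **`quorum.standards`** — the human reference workflow: dual review plus
  adjudication (*gold standard*), and its revision into a *platinum
  standard* by flagging items where ≥ 4 raters of the full pool agree on an
  answer that contradicts gold, then accepting or rejecting each flag.
- **`quorum.llm_io`** — prompt assembly (role, task context, JSON output
  schema with an explanation field first, few-shot examples) and a total,
  never-raising parser from raw model text to normalized answers.
- **`quorum.simulate`** — a calibrated synthetic generator: raters with
  logit-scale abilities, shared per-item difficulty (so errors correlate on
  hard items), diverse extraction error modes, format failures, and
  simulated human reviewers under the same law — plus an exact multinomial
  oracle for the consensus rule under independence.

## The rule

For item *i* let each panel member return an answer (a label, a
non-negative integer, or `missing`). With tally counts
*c(v)* over valid responses, the consensus is

```
decide(i) = v   if c(v) ≥ T and v is the only such value
withhold(i)     otherwise
```

For a binary label set any T > N/2 makes the winner automatically unique.
Raising T trades coverage for accuracy monotonically: the decided set at
T+1 is always a subset of the decided set at T.

## Worked example

```python
from quorum import (default_config, simulate_study, ConsensusRule,
                    decide_batch, score_decisions, truth_from_frame)

cfg = default_config("categorical", seed=7, n_items=1020)
ds = simulate_study(cfg)   # truth, 8-rater responses, human reviews

panel = ["llm1", "llm3", "llm5", "llm6", "llm8"]
sub = ds.responses[ds.responses.rater_id.isin(panel)]
decisions = decide_batch(sub, ConsensusRule(n_models=5, threshold=4))
report = score_decisions(decisions, truth_from_frame(ds.truth))
print(f"decided {report.n_decided}/{report.n_items} items "
      f"(coverage {report.coverage:.1%})")
print(f"accuracy on decided items: {report.accuracy_decided:.1%}")
print(f"accuracy over all items:   {report.accuracy_overall:.1%}")
```

prints

```
decided 897/1020 items (coverage 87.9%)
accuracy on decided items: 99.1%
accuracy over all items:   87.2%
```

— a 4-of-5 panel decides ~88% of items and is right on 99% of those it
decides, even though its best member is only ~95% accurate alone. The
withheld 12% are exactly the items a human should look at.

The same workflow is scriptable from the shell:

```bash
quorum simulate --task categorical --n-items 1020 --seed 7 --out study/
quorum sweep --responses study/responses.csv --truth study/truth.csv --out sweep/
quorum revise --responses study/responses.csv --reviews study/reviews.csv --out rev/
# edit rev/ledger.csv outcomes, then finalize:
quorum revise --responses study/responses.csv --gold rev/gold.csv \
              --ledger rev/ledger.csv --out rev/
```

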