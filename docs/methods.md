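# Methods

## The decision model

`quorum` implements unweighted threshold voting with abstention over a
panel of N raters. A response to an item is one of: a valid answer (a
categorical label; or, for extraction tasks, a non-negative integer or the
distinguished token `missing`), a *format issue* (the rater produced
unparseable output), or no response. The rule:

- tally exact-match counts over **valid** responses only; `missing` is an
  ordinary, countable answer; format issues and absent responses occupy a
  panel slot but never support any value, so a panel with *f* failures can
  only decide when T ≤ N − *f*;
- decide for value *v* iff *v* is the **unique** value whose count reaches
  the threshold T; otherwise withhold. Ties at the threshold (possible for
  extraction answers, or for categorical tasks with T ≤ N/2) are withheld:
  the rule produces *an* answer or none, never a choice among several.
- extraction equality is exact integer equality after normalization — no
  tolerance. Normalization (case-folding labels, stripping thousands
  separators, mapping configured "missing" spellings) happens at parse
  time, so the core never compares formatted strings.

Consequences used throughout the tests: for a binary label set and
T > ⌊N/2⌋, at most one label can reach T (pigeonhole), so a reached
threshold always decides; the decided set shrinks weakly as T grows; and
on counts, `accuracy_overall = accuracy_decided × coverage` exactly.

Two accuracy denominators are deliberately both first-class. A
selective-prediction system is naturally judged on the items it decides
(`accuracy_decided`, the headline number here) but can also be judged on
all items with abstentions counted as failures (`accuracy_overall`). The
package computes both from integer counts and only rounds (to one decimal
of a percent) at the reporting layer.

## Sweeps

A sweep evaluates every rater subset of each requested size — C(8, N) =
56, 70, 56, 28, 8 subsets for N = 3…7 of an 8-rater pool — at every
threshold in the grid. The default grid runs from **strict majority**
⌊N/2⌋+1 to unanimity N. A grid reaching below strict majority would allow
ambiguous binary votes (two labels reaching T simultaneously); an
`explicit` policy accepts any other grid where that reading is wanted.
Summaries report the median and quartiles over subsets per (N, T), with
linear interpolation between order statistics (the quantile convention is
stated because different statistical environments default differently).

The sweep engine is vectorized (integer code matrices; a panel's tallies
are column-vs-column equality counts), which keeps a full five-size sweep
over 10,000 items around a second. The engine is *not* trusted on its own:
the suite asserts row-for-row equality with the plain per-item decision
route on fixtures of both tasks.

## Reference standards

The **gold standard** is dual independent review with third-reviewer
adjudication of disagreements. The **platinum standard** revises gold where
the panel strongly disagrees: an item is flagged when at least
`flag_threshold` raters (default 4) of the **full pool** give the identical
answer and that answer differs from gold. Flagging always uses the full
pool — a sweep subset would produce as many flagged sets as panels. Each
flag is accepted or rejected by a fourth reviewer (an input; a simulation
hook resolves flags against known truth for end-to-end tests). Accounting
identities maintained on counts: flagged = accepted + rejected;
gold-vs-platinum accuracy = 1 − accepted/items; and per class,
final = initial − outflow + inflow with class totals conserved.

## The simulator

The generator exists so that every other module is testable, with known
truth, at any scale, without any model inference. It emulates:

- **Rater heterogeneity.** Each rater has an ability *a* on the logit
  scale. Default panel: 8 raters calibrated to marginal accuracies
  {0.95, 0.94, 0.93, 0.92, 0.90, 0.88, 0.85, 0.80} — the band small
  open-weight models span on these tasks.
- **Correlated errors via item difficulty (Rasch-style).** Item *i* draws
  difficulty d_i ~ Normal(0, 1); rater *r* answers correctly with
  probability sigmoid(a_r − d_i). A shared difficulty is the simplest
  mechanism that reproduces the phenomena that matter here — hard items
  defeat several raters at once, and the same hard items defeat the human
  reviewers, which is why revision flags concentrate on adjudicated items.
  The difficulty SD of 1.0 is a free parameter (nothing in the data model
  pins it); it is exposed in `SimConfig`, and directional claims in the
  tests do not depend on its exact value.
- **Diverse wrong answers.** Categorical errors flip to the other label
  (binary task). Extraction errors draw from a mode mixture: report a
  single arm's size (`one_arm`), an arithmetic slip of ±1–10, a corrupted
  digit, or a spurious `missing` — weights 0.3/0.3/0.3/0.1 by default.
  Items that require summing per-arm counts reweight to 0.6/0.15/0.15/0.1
  (the signature error there is forgetting to add the arms). With these
  modes, two independently wrong raters rarely coincide, which is exactly
  why extraction consensus is so precise and why the tests can assert a
  coincidence rate below 0.1 of the joint error rate.
- **Calculation burden.** Requires-calculation items (probability 0.30 —
  roughly the fraction of abstracts reporting arms separately) subtract a
  penalty from ability: 0.4 logits for machine raters (a few points of
  accuracy), 2.0 logits for humans (a ~20-point drop), reproducing the
  contrast where adjudicated human references lose far more accuracy on
  such items than the panel consensus does.
- **Format failures.** Each response is replaced by a format issue with a
  per-rater probability: 0.005 for seven raters and 0.05 for one — the
  one-problematic-model pattern real panels show.
- **Truth model.** Binary labels with drug prevalence 0.44; extraction
  truths are sums of two arms drawn uniformly from 20–300 (arbitrary but
  stated; configurable); 22/1020 of items report no sample size
  (truth `missing`). When truth is `missing`, a wrong answer is a
  hallucinated plausible total.
- **Humans.** Two reviewers and an adjudicator follow the same
  difficulty–ability law. Reviewer abilities are calibrated to 0.90
  marginal accuracy (classification) / 0.94 (extraction); the adjudicator
  ability is solved by root-finding so adjudicated gold accuracy lands at
  0.96 / 0.98 under the binary agreement law *before* the human
  calculation penalty — with the penalty active, extraction gold lands a
  few points lower, which is the intended behaviour, not a calibration
  error.

Calibration inverts E_d[sigmoid(a − d)] = target by Brent's method with
Gauss–Hermite quadrature (101 nodes, |error| < 1e−6); the point-mass case
reduces to the logit identity. All draws flow from a single mandatory seed
through spawned substreams (truth, panel, reviews), so identical configs
give byte-identical tables.

**What the simulator does not model** — and hence what passing tests do
not show about real data: actual model text or rationales, prompt
sensitivity, systematic shared biases beyond the difficulty channel (two
models fine-tuned from the same base could make *identical* wrong
extractions more often than independence predicts), non-uniform journal or
domain effects, and drift over time. Results on synthetic panels
demonstrate the framework's mechanics and internal consistency, not the
accuracy any particular model panel will achieve.

## Analytic oracle

`analytic_consensus_probability(p, n, t, k)` computes exact
(decided-correct, decided-wrong, withheld) probabilities for n iid raters
that are correct with probability p and otherwise uniform over k wrong
alternatives, by multinomial enumeration. It exists purely as an
independent check: the Monte-Carlo generator must agree with it within
sampling error in the iid regime (flat difficulty), and the binary task
with k = 1 ties it directly to `simulate_panel`.

## Numerical and design choices

- Quantiles: linear interpolation; documented because the convention
  affects published medians at the third decimal.
- F1 is defined as 0 when precision + recall = 0 (logged; does not occur
  in calibrated runs).
- Per-class precision/recall are computed over decided items only —
  abstentions are not predictions. For extraction tasks, classification-
  style metrics collapse to `missing` vs `reported` (one-vs-rest), the
  only classes with stable meaning over an unbounded answer alphabet.
- Flag threshold semantics are ≥ 4 (not > 4), configurable; with 8 raters
  and the ≥-reading the flagged set is well-defined from the full pool.
- Items may have fewer response rows than `n_models` (raters drop out);
  the threshold still refers to the panel size, not to rows present.
- Word numerals ("two hundred") are not parsed; only the first balanced
  JSON object in a model's output is used (logged when several appear);
  per-arm numbers are never summed by the parser — arithmetic is the
  rater's job, and a parser that silently "fixed" totals would corrupt
  the exact-match semantics.
- Problem sizes: unit fixtures use 150-item studies; Monte-Carlo and
  frontier checks use 10,000 items, where binomial noise on a 0.9
  proportion is ±0.3 percentage points (1 SE) — small enough for the
  stated tolerances while keeping the whole suite fast.

## Known limitations

- The consensus rule is unweighted by design; reliability-weighted or
  probabilistic (Dawid–Skene-style) aggregation is out of scope.
- The revision workflow models a single fourth-reviewer pass; reviewer
  bias and identifiability are not modelled.
- The analytic oracle covers iid raters only; no closed form is provided
  under shared difficulty (the Monte-Carlo path covers that regime).
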