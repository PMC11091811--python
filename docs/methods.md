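# Methods

This note documents the models, conventions and numerical choices behind
`ddxbench`, and what the synthetic-data tests do and do not establish.

## Vignette model and standardization

A vignette carries the eight components of the standard clinical-vignette
design: age and sex, 1–3 chief complaints, present findings, absent
findings, basic (physical-exam) findings, past history, family history,
and the gold main + differential diagnoses. The *gold ranked list* used by
every metric is `[gold_main] + gold_differential` in stored order: the
main diagnosis is rank 1 of the ideal answer (M1 demands exactly that),
and the differential follows in its adjudicated order. Whether recall
should be computed including the main diagnosis is not uniquely
determined by the study design; we include it by default and expose
`include_main=False` on `gold_ranked_list` and the regime functions for
the alternative.

Standardization is a supermajority vote: a vignette becomes gold iff at
least `accept_threshold` of `panel_size` reviewers (defaults 5 of 7)
accept it in the **latest** full-panel round. A revised vignette needs a
fresh full-panel round — we do not model partial re-review by prior
rejectors, since the workflow's intent there is not recoverable. The
status machine is `draft → under_review → (gold | revision →
under_review → …)`; only gold vignettes are scoreable.

Serialization: JSON is canonical (`{schema_version, vignettes: [...]}`,
fixed field order, 2-space indent), so write∘read∘write is byte-stable;
the CSV dialect flattens list fields with `|`.

## Match adjudication

Labels are normalized by Unicode NFKC, case-folding, punctuation
stripping and whitespace collapsing, then resolved through the lexicon's
synonym table. A prediction matches a gold disease when (a) the canonical
keys are equal, (b) the prediction's entry lists the gold disease under
`umbrella_of`, or (c) the two are listed as related. Three deliberate
restrictions:

- **Directionality.** An umbrella prediction matches a specific gold
  disease; a specific prediction does *not* match an umbrella gold label
  (raters are judged on their output against the gold entry, not the
  reverse). Pairs that should match both ways belong in `related`.
- **One hop only.** No umbrella-of-umbrella or related-of-related
  chaining — "directly related" means one edge.
- **Graceful degradation.** Unknown labels fall back to exact
  canonical-string equality, so the engine works without any lexicon.

Structural validation: synonym sets must be disjoint across entries,
`related` is symmetrized on load, `umbrella_of` must be acyclic. Mapping
to external terminologies (ICD, SNOMED) and fuzzy matching are out of
scope; the breadth of "directly related" is the lexicon author's call.

## Metrics

Per-vignette values are fractions in [0, 1]; aggregates multiply by 100.
Conventions that matter:

- **Consumption.** A gold disease's credit/relevance is consumed by the
  first differential entry that matches it; later duplicates earn nothing
  but still inflate the precision denominator.
- **Empty differentials** score 0 on every metric (required so the
  all-vignettes regime genuinely penalizes failed sessions). Hence
  precision uses the 0-for-empty convention rather than being undefined.
- **DCG discount** is the standard `log2(rank + 1)` (discount 1 at rank
  1); relevance is `n − i + 1` for gold position `i`, anchored to the
  2-disease example (relevancies 2 and 1). With these, the gold ordering
  maximizes DCG over all permutations — verified by exhaustive
  enumeration up to n = 6 — so NDCG ∈ [0, 1] needs no clipping.
- **F1** is the harmonic mean of the aggregate average recall and
  precision, *not* the average of per-vignette F1 values. This is the
  convention under which each published rater's F1 follows exactly from
  its published recall and precision, and it keeps F1 between the two
  averages.
- **Reporting** rounds half-up (`decimal`, not banker's rounding): one
  decimal for percentages, integers for group SDs. All arithmetic is done
  unrounded; rounding is presentation-only.

## Failure taxonomy and regimes

Session statuses: `ok`, `no_ddx` (session concluded without a
differential), `crash`, `search_limit`, `age_limit`. The failure table
requires exactly one output per vignette, so the five counts sum to the
suite size by construction. Question-count statistics (mean, sample SD
over non-crashed sessions with a recorded count) are descriptive only.

- **all**: every vignette in the denominator; non-ok sessions contribute
  all-zero metrics.
- **succeeded**: `search_limit`/`age_limit`/`crash` leave the
  denominator; `no_ddx` stays and scores zero (the session succeeded,
  the diagnosis did not).
- **intersection**: the evaluation set is the intersection of the
  included raters' ok-sets; each included rater is summarized on exactly
  that set. An empty intersection raises, never silently returns. Raters
  with extreme no-differential rates should be left out of `include` so
  they do not collapse the set — exclusion is a configuration choice,
  not hard-coded.

Two identities follow from the definitions and are tested exactly (not
statistically): succeeded-only never scores below all-vignettes on any
metric, and for the indicator metrics `all = succeeded × kept/N` where
`kept = ok + no_ddx`.

## Synthetic data generator

The generator produces the study conditions end to end: a suite
(default 400 vignettes) spread over the 14 body systems with the
benchmark's weightages (multinomial by default; a
`deterministic_proportions` flag gives largest-remainder exact counts),
common/less-common flags at the benchmark's 55.5% common rate, gold
differential lengths drawn from a pmf (default support 1–5, mode 3), and
a lexicon giving a configurable fraction of diseases a synonym (30%) and
an umbrella term (15%).

A simulated rater is controlled by a skill profile: cumulative
probabilities `p_top1 ≤ p_top3 ≤ p_top5` that the main diagnosis lands
within ranks 1/3/5 (defaults 0.6/0.8/0.9, roughly the strongest raters
in published studies; uniform rank within the 2–3 and 4–5 bands, omitted
with probability `1 − p_top5`), per-disease inclusion probability
`gold_recall_q` for the rest of the gold list, a distractor-count pmf,
mutually exclusive failure-category rates, and a label-noise rate at
which a synonym or umbrella variant is emitted instead of the canonical
name. Included gold diseases keep their gold relative order — a rater
who recalls the full list in order earns NDCG exactly 1 — while
distractors are interleaved at random positions, which is what degrades
ranking quality. Determinism: one master seed; each rater/replicate
derives an independent substream by hashing its id into the seed
sequence, so adding a rater never perturbs another's draws.

Because every parameter is known, closed forms exist for the pipeline's
expected output: under the all-vignettes regime E[M@k] = `p_topk (1 − f)`
with `f` the total failure rate, and a vignette with gold length `n` has
expected recall `(p_top5 + (n−1) q)/n · (1 − f)`. `recovery_report`
simulates replicate raters, scores them with the real pipeline, and
flags any parameter whose pooled estimate falls more than 3 standard
errors (SE of the replicate mean) from its expectation. The acceptance
run uses 500 replicates on a 400-vignette suite (~30 s on one CPU);
unit tests use smaller designs.

What passing these tests shows — and does not. They establish that the
scoring pipeline is an unbiased measurement instrument for raters whose
behaviour follows the profile model, and that the regime arithmetic and
ranking metric are implemented exactly. They say nothing about real
symptom checkers: synthetic labels carry no medical semantics, failure
categories are drawn independently of case content (real search/age
failures correlate with body system and age), rank placement is
independent of disease difficulty, and the lexicon is complete by
construction, whereas real adjudication depends on a curated lexicon's
coverage.

## Group statistics

Group summaries use the **population** SD (divisor n): on the physician
M1 column {49.7, 61.3, 72.5} the population SD is 9.31 (printed 9) while
the sample SD would be 11.4 — the published tables fix the convention.
Relative outperformance is always baseline-denominated,
`100·(a−b)/b` on unrounded aggregates; the one published sentence that is
winner-denominated (the precision comparison) is treated as an
inconsistency and not emulated. Orderings sort on unrounded values and
render raters as a tie group when their values coincide at the reported
precision (one decimal). Published outperformance ratios were evidently
computed from unrounded aggregates, so recomputing them from the rounded
printed values can differ in the last digit (e.g. 10.29 vs a printed
10.2); exact reproduction of those ratios is therefore not asserted.

## Problem sizes

Default test and acceptance runs use: exhaustive permutation oracles up
to n = 6; 200 random small suites (≤ 8 vignettes) for the
independent-aggregator comparison; 150-vignette simulations for the
regime identities; and 500 × 400 sessions for parameter recovery. These
sizes give sub-percent standard errors on every recovered parameter
while keeping the full suite comfortably fast on a single CPU.

## Known limitations

- The match engine is lexicon-bound: adjudication quality is the
  lexicon's quality, and no fuzzy matching softens misspellings.
- `no_ddx` sessions carry no partial credit even if the rater named a
  diagnosis outside a formal differential.
- The intersection regime compares raters on a set that depends on which
  raters are included; summaries from different `include` sets are not
  comparable with each other.
- Group statistics are descriptive (means, ranges, SDs, orderings); no
  significance testing across raters is provided, matching the study
  design the framework implements.
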