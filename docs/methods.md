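# Methods

## Setting

Seventeen-odd public missense pathogenicity predictors differ in three ways
that matter for benchmarking beyond raw correctness: (i) output vocabulary —
word labels versus numeric scores, with program-specific synonym sets;
(ii) coverage — many programs produce no output for variants lacking a
premade HMM, a solved protein structure, or the queried isoform; and
(iii) hedging — "possible" calls and 0–9 reliability indices that make a
prediction technically present but clinically unusable. `predbench`
evaluates predictors on curated two-class variant sets while accounting for
all three.

## Credibility classification

Variants enter the benchmark through a deterministic rule engine
(`variant_model.classify_variant`), not through any external database query.
The evidence record is user-supplied: publication/database status, clinical
observation, in-house sequencing confirmation, the count of large population
resources reporting the variant, the maximum reported MAF, and dbSNP
validation. The pathogenic and benign rules are conjunctions as documented
in the module; three numerical choices deserve note:

* **Strict MAF comparison.** "Greater than" is implemented as `>`; a MAF
  exactly at the threshold never yields credibly benign.
* **Panel-specific thresholds** default to 0.001 (dominant gain-of-function
  panel) and 0.010 (recessive loss-of-function panel), configurable via
  `ClassificationConfig`.
* **Conflicts.** If both rule sets fire the variant is returned
  `unclassified`, never silently assigned one class; properly curated
  datasets have disjoint classes by construction, so a conflict indicates a
  curation error worth surfacing.

Classification is a pure function and is tested against an exhaustive
truth-table oracle (all 2^7 boolean evidence combinations × MAF
below/at/above threshold × both panels).

## Harmonization

Word labels are normalized (case, whitespace) and looked up in a per-program
vocabulary; the shipped default maps
{probably damaging, damaging, pathological, deleterious, disease-causing,
disease, non-neutral} → Damaging, {possibly damaging, possibly deleterious} →
PossiblyDamaging, and {benign, tolerated, non-deleterious, polymorphism,
neutral} → Benign, with empty/N-A cells → Missing. Unknown labels are hard
errors naming the program and label: silent coercion to Missing would corrupt
the VarCall denominator.

Numeric programs use per-program damaging/benign score bands with
individually open/closed ends (closed by default); scores in neither band
are PossiblyDamaging, and overlapping bands are rejected at config-load
time. The authoritative per-program cutoffs for the original score-based
programs are not publicly recoverable, so the shipped numeric defaults are
illustrative and the band mechanism is the contract.

The reliability cutoff defaults to **≥ 5** on the 0–9 scale. The threshold
is inclusive — a score of exactly 5 counts as the mid-to-high band on a
0–9 scale — and configurable per program, so the exclusive alternative is
one flag away. A reliability-scored record with no index is treated as
unreliable. Usability is the conjunction: `usable = (call ∈ {Damaging,
Benign}) and reliable`. Raising the threshold can only shrink the usable
set (a property test asserts this monotonicity).

## Metrics

TP/FP/TN/FN are counted over usable calls only; `VarCall` counts variants
with any non-Missing output; `VarUse = TP+FP+TN+FN`. The seven statistics
are the standard confusion-matrix ratios plus `PWeight = VarUse/VarCall` and
`WAccuracy = Accuracy × PWeight`.

* **Undefined, not zero.** Any metric with a zero denominator is `None` and
  propagates (WAccuracy is undefined when Accuracy is); substituting 0 or 1
  would silently distort rankings.
* **Unrounded intermediates.** WAccuracy is the product of unrounded
  accuracy and performance weight, algebraically `(TP+TN)/VarCall`. This
  matters at the third decimal: e.g. 56/61 × 61/68 = 56/68 rounds to 0.824,
  whereas the product of the two rounded factors (0.918 × 0.897) would round
  to 0.823.
* **Half-up report rounding.** Tables round half-up at 3 decimals and
  percentages at 1 decimal, only at report time (`round_report`).
* **Per-class correctness** (the bar-chart statistic) deliberately uses a
  different denominator: variants of the class with *any* non-Missing
  output, including possible and unreliable calls; the numerator is correct
  usable calls.
* **Pooling across panels** sums confusion counts and coverage counts, never
  averages per-panel metrics; with the shipped fixtures this reproduces the
  combined 100/121 = 82.6% exactly.

## Consensus

For a triple of programs (default MutPred / Condel / FATHMM-Weighted, any
three names accepted), each variant is bucketed by its pattern of correct
and incorrect usable calls. Correct requires a usable call matching the
credibility label; possible and unreliable calls count as neither. Variants
with ≥ 2 Missing calls are excluded; exactly-two-way agreement tolerates a
third call that is incorrect, possible, unreliable, or missing; one correct
plus one incorrect plus anything non-usable is inconsistent (no two usable
calls agree). The summary reports the trustworthy-correct fraction
(all-correct + two-correct over evaluated variants) and a strict variant
that also drops inconsistent variants from the denominator. Pairwise
concordance is the fraction of shared variants on which both programs'
calls are usable and identical.

No weighting, score averaging, or >3-program voting is implemented: the
object of study is the fixed three-program scheme, whose combined
trustworthy-correct percentage on the shipped fixtures equals the best
single program's pooled weighted accuracy (both 100/121) — the negative
finding the acceptance tests pin down.

## Synthetic data

`generate_dataset` emulates the study conditions: two panels of 35 + 19 and
36 + 32 pathogenic/benign variants whose evidence columns are generated to
re-classify to the intended labels, scored by k program profiles. Per
variant × program the generator draws, in order: forced missingness when the
program is structure-dependent and the gene lacks a solved structure
(gene-granular, matching how structure-based predictors fail), Bernoulli
missingness at `1 − call_rate`, a "possible" call at `possible_rate`,
otherwise a dichotomous call correct with probability `sensitivity`
(pathogenic variants) or `specificity` (benign). Reliability indices are
drawn from a per-program distribution, uniform over 0–9 by default since no
empirical distribution is available. All draws come from one
`numpy.random.default_rng(seed)` stream; identical seeds give identical
tables.

Inter-program correlation is off by default; an optional shared-uniform
copula (`correlation` = probability a variant's correctness draw is shared
across programs) is provided as an artifact convention for studying
concordance, not as an empirical model.

What the generator does **not** emulate: real per-program score
distributions, training-set overlap between predictors and the benchmark
variants, position- or gene-specific difficulty, and any realistic
dependence structure between programs. Tests passing on synthetic data
therefore validate the bookkeeping (harmonization, counting, weighting,
consensus logic), not the field performance of any predictor.

`build_fixture` is the deterministic counterpart: it emits exactly the
requested TP/FP/TN/FN usable records plus `n_possible` possible and
`n_missing` missing records (hedged/missing records alternate between the
two classes), so any published confusion composition can be replayed through
the full pipeline bit-exactly; a round-trip property test asserts
tabulation recovers the requested counts for arbitrary compositions.

## Problem sizes and determinism

The test suite runs the exhaustive classification truth table (2^7 × 3 MAF
positions × 2 source counts × 2 panels), counting-oracle comparisons on
random datasets up to 200 variants × 5 programs, and generator parameter
recovery pooled over ~30 replicates of the 122-variant study design
(≥ 2000 class draws, ±0.03 tolerance ≈ 3–4 binomial standard errors at
n = 2000). The acceptance script's statistics are order-invariant, so its
output is identical across seeds; the seed only shuffles record order before
tabulation.

## Known limitations

* Credibility evidence is user-asserted; no live dbSNP/Ensembl/HGMD lookups
  are performed, and no ACMG/AMP-style weighted classification is attempted.
* HGVS strings are validated-format opaque text; no transcript mapping.
* Numeric-band defaults are illustrative, not the original programs'
  cutoffs.
* The consensus scheme is fixed at three programs; ROC/AUC analysis is out
  of scope because the evaluation dichotomizes all outputs.
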