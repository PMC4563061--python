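# Methods

## Problem and formulation

Section headings in clinical notes are contiguous character spans — label
plus attached punctuation and parentheses, e.g. `"Chief Complaints:"`,
`"Meds (Updated 7/20)"` — and more than half of them share a line with
other content. We therefore label *tokens*, not lines: each physical line
is a sequence, each token receives an IOB2 tag, and decoded `B I*` runs
become predicted spans. This separates a heading from surrounding content
in one decoding pass, with no post-hoc heuristics to trim the heading out
of a "section-start" line.

One CRF sequence is one physical line. Headings never cross line breaks in
this data model, blank lines carry no tokens (they are skipped for training
but retained for layout features), and short per-line sequences keep exact
inference cheap and batchable.

## Text model

- Character offsets are 0-based half-open everywhere, matching brat
  standoff conventions. `\n`, `\r\n` and `\r` line endings are all
  accepted; emitted files use `\n`.
- Tokenization is a deterministic rule: maximal alphabetic runs, maximal
  digit runs, single punctuation characters; whitespace is consumed. The
  method needs token boundaries and offsets only, so no part-of-speech
  tagger is involved. (A consequence: a digit string like `88` is one
  token here; systems built on POS tokenizers may split it differently.
  All span-level outputs are unaffected.)
- Gold spans are projected to tags by token *start* offset: the token
  starting a span gets B, tokens starting strictly inside get I. This
  keeps alignment total and deterministic when a span boundary falls
  inside a merged token; a span covering no token start raises (strict) or
  is logged and skipped (lenient, the training default — such spans are
  exactly the token-fusion transcription artifacts, which are unlearnable
  at token level and cost one FN each at evaluation).
- Decoding repairs an orphan I (after O or at sequence start) as B, the
  standard chunking convention, so any tag sequence decodes.

## Features

All features are presence-encoded (the name carries the value); each
feature name pairs with the current tag, and a single tag-bigram template
supplies transitions.

| family | content | default |
|---|---|---|
| word | normalized surfaces at offsets −2..+2; `<S>`/`</S>` sentinels at edges | on, window 2 |
| affix | 2-character prefix and suffix, case preserved (`PSurHx` → `PS`, `Hx`) | on |
| ortho | ALLCAPS, CAPSMIX, INITCAP, PUNCTUATION (`.` or `:`) | on |
| lexicon | substring match against the terminology, best entry's level and normalized concept, 3-bit occurrence code | on |
| semantic | per-line physician marker: `M\s?\.?\s?D\s?\.?`, `Dr\s?\.?`, or `PCP` as substring | on |
| layout | `blank[k]` for k in −3..−1, +1..+3: is the line at that offset blank | on, block 6 |

Normalization lowercases and collapses every digit run to `1`. CAPSMIX is
read as mixed case *beyond* initial capitalization, so `SocHx` fires and
`Date` does not; this keeps ALLCAPS ⇒ ¬CAPSMIX. The occurrence code reads
(last, middle, first) bits of where a token ever appears inside terminology
headings; a single-token heading counts as both first and last, which makes
the eight code values exhaustive. Lexicon substring matching is
case-insensitive, token ⊆ term; ties among containing terms go to the
longest, then lexicographically first — deterministic and biased toward
specific headings. The physician-marker flag is computed per line and
attached to each of its tokens. The marker pattern deliberately matches a
bare `Dr` prefix; it is a weak feature the CRF weighs, not a rule.

## CRF

`p(Y|W) ∝ exp Σ_t [ Σ_i λ_i f_i(t) + λ_{y_{t−1},y_t} ]` with a virtual
START state at t=0 and no STOP state. Training minimizes the negative
conditional log-likelihood plus `c·‖λ‖²` (default c = 1.0) by L-BFGS-B on
exact gradients; marginals come from forward–backward run in log space,
batched over sequences grouped by length, with unigram scores through one
sparse design matrix. The objective is convex; optimization is
deterministic given data order, and `seed` is recorded in model metadata
for upstream sampling provenance only. Default cap of 200 iterations
(typically converges in well under 100 on the synthetic corpora).
Viterbi breaks ties toward the first label in B < I < O at every backtrack
step — equivalently, among tied maximum-score paths it returns the one
minimal in reversed-position lexicographic order — so outputs are
bit-reproducible. Unknown features at prediction time score 0. Models
serialize to a flat JSON of labels, weights and metadata.

The optimizer is treated as pluggable behind the stated objective; this
implementation is bespoke (scipy L-BFGS-B) and is validated against
brute-force enumeration oracles: Viterbi scores equal enumerated maxima,
the forward log-partition matches enumeration to 1e-8 relative, and the
implied distribution sums to 1 on all sequences short enough to enumerate.

## Dictionary baselines

Term expansion produces, per term: the original, Title Case, Sentence
case, lowercase; a base form of each (final word de-pluralized — strip a
trailing `s` unless `ss`; no lemmatizer, documented as approximate);
stop-word-free variants (default stop list `and, of, the, for, at, on,
in`); and every variant suffixed with `:` and `.`. Method 1 scans each
line left to right taking the longest token-boundary-aligned exact match
at each position. Method 2 keeps only matches starting at the first
non-whitespace character of a paragraph-initial line — first non-blank
line of the note, or a line whose immediately preceding line is blank
("beginning of a paragraph" is not otherwise defined, so this is the
package's definition). Whether the original maximum matching operated on
characters or tokens is unrecorded; token-boundary alignment is the choice
here. Matching is case-sensitive over the expanded forms (the expansion
carries the case variants).

## Evaluation

Exact-span matching on character intervals: TP are predicted intervals
identical to gold intervals; every other prediction is an FP and every
unmatched gold span an FN, so one boundary error costs one of each.
P = TP/(TP+FP), R = TP/(TP+FN), F harmonic; zero denominators yield 0 by
explicit convention. Duplicate predicted intervals are collapsed before
scoring. Corpus scores are micro-averages (pooled counts).

## Synthetic corpus generator

The generator emulates the *structural* statistics reported for real
discharge-summary corpora, not their language:

- `mean_sections_per_doc = 10.7`, drawn Poisson (only the mean is known;
  Poisson is a modeling choice), minimum 1.
- `inline_heading_rate = 0.556`: probability a heading is embedded
  mid-line flush against preceding content (the published single-line vs
  inline percentages, 44.32% + 55.58%, sum to 99.9% by rounding; the rates
  are normalized to sum to 1). The flush attachment lands after a
  sentence-final period, so a clean token boundary survives.
- `novel_heading_rate = 0.08` of paragraph-initial sections use a heading
  outside the vocabulary/terminology (e.g. `HCP/FAMILY CONTACT`); these
  are always placed with clear paragraph layout, which is precisely the
  signal the layout features exist to exploit. Applying the rate only to
  paragraph-initial draws keeps the realized inline fraction at its
  configured value.
- `supplemental_insert_rate = 0.10` adds parenthetical supplements
  (`"(Updated 7/20)"`-style); gold spans include the parentheses and any
  trailing colon.
- `tokenization_noise_rate = 0.02`: an inline heading's first token is
  fused to the preceding word (`...monitorHabits...`), emulating
  transcription artifacts; gold offsets are computed after corruption, so
  these spans start mid-token and are unrecoverable by a token-level
  tagger — they bound achievable recall by design.
- Heading rendering: canonical Title Case, ALL CAPS, or a clinical
  abbreviation (CC, HPI, ROS, PMH, FHx, SocHx, PE, ALL, ...), with a colon
  70% of the time. Content is filler over pseudo-clinical word lists
  (symptoms, medications, exam phrases) that deliberately collide with
  single-word heading terms ("data", "plan", "habits", "diet") so
  dictionary matching exhibits its characteristic precision loss. No real
  patient text is involved.
- Splits follow a 521/269/514 train/dev/test partition, scaled and
  rounded (100 notes → 40/21/39). One numpy Generator drives everything;
  a fixed seed reproduces the corpus byte for byte.

What passing tests on this corpus do **not** show: robustness to real
clinical language (misspellings, domain abbreviations in content,
section-heading ambiguity across document types), to heading vocabularies
larger than ~60 concepts, or to layout conventions other than
blank-line-separated paragraphs. Held-out F on the synthetic corpus
(≈0.97–0.99) is an upper bound driven by its limited heading vocabulary;
the corresponding figure on real notes is substantially lower. Because
lexicon and word features nearly saturate performance here, the measured
layout-ablation delta is small (and can sit within noise on some seeds),
whereas on real data with richer unseen-heading tails the layout family
matters more.

## Problem sizes and defaults

The shipped evaluation pipeline (`scripts/acceptance.py` and the
corpus-level tests) trains on 300 synthetic notes (~7 500 line sequences,
~1 500 features) and evaluates on 100 held-out notes; L-BFGS capped at 150
iterations. These sizes give stable corpus-level scores (gold span counts
≈ 1 000 per test split) while keeping a full run in tens of seconds.
Regularization 1.0 and the feature defaults above are used unchanged
throughout; no per-dataset tuning is performed.

## Known limitations

- Headings spanning multiple physical lines are out of scope by the data
  model.
- Token-fusion artifacts make the affected spans unlearnable at token
  level (cost: one FN, and typically one FP from the partial prediction).
- The terminology TSV (heading, normalized concept, hierarchy level) is a
  stand-in schema for published section-header terminologies; levels are
  used only as discrete feature values.
- Dictionary base-form generation is naive de-pluralization, not
  lemmatization.
- No heading normalization to canonical section categories: the package
  finds spans, it does not classify them.
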