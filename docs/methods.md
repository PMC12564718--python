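# Methods

`racnlp` implements a three-path clinical-NLP pipeline for malnutrition
surveillance in residential aged care (RAC): domain-adaptive
masked-language-model (MLM) pretraining on nursing notes, a
malnutrition-note classifier, and a malnutrition predictor that fuses a
pooled text embedding of a 30-day note window with a structured
risk-factor vector. This note records the model, its assumptions, the
defaults that matter, and the design decisions taken where the design
was genuinely open.

## Encoder and tokenisation

The text encoder is a compact bidirectional transformer written
directly over NumPy with a small reverse-mode autodiff core
(`racnlp.autodiff`): token + learned positional embeddings,
pre-LayerNorm multi-head self-attention with an additive padding mask,
GELU feed-forward blocks, and a final LayerNorm. The default "tiny"
profile is 2 layers, 4 heads, width 64, feed-forward 128, maximum
sequence length 512 — sized so that pretraining and fine-tuning run in
minutes on one CPU core. All arithmetic is float64, which lets the
pooling identities below hold to 1e-5–1e-12 tolerances in the tests.

Tokenisation is a WordPiece-style scheme trained on the corpus:
frequent whole words are single tokens; other words decompose greedily
into pieces (`##` continuations), with single characters guaranteeing
coverage. The tokeniser also returns a word-id per token — all subwords
of one whitespace word share an id — which is the alignment whole-word
masking needs. A byte-level BPE would serve equally; the word-id
contract is the only property downstream code relies on.

## Path 1 — domain-adaptive pretraining

Cleaned notes are concatenated into a single token stream and cut into
consecutive 512-token rows; the final partial row is kept and padded
(`--drop-remainder` discards it instead — the choice is immaterial to
everything downstream, keeping data is the safer default). Rows are
split 80/20 into train/validation.

Masking is whole-word at probability 0.15 per word: every subword of a
selected word is corrupted together, with the standard 80% [MASK] /
10% random token / 10% keep split decided once per word. The corruption
split and the convergence rule are not pinned down by the task
definition, so both are recorded as configurable defaults rather than
claims: early stopping triggers when relative validation-loss
improvement over 5 evaluations falls below 0.5%. Mask patterns are
redrawn every time a chunk is served, so no fixed corruption can be
memorised across epochs. Default optimiser settings: AdamW, learning
rate 1e-4, batch size 32, weight decay 0.01 (decay on matrices only,
never biases or LayerNorm gains).

## Long-note encoding (chunk-and-aggregate)

Aggregated 30-day windows average ~644 tokens and routinely exceed the
512-position limit. A note's content tokens are split into equal
512-position parts; each part carries its own start and end token, so
content capacity per part is 510 and the part count is ceil(C/510).
The final part is padded, with attention mask 0 on padding. Each part
is encoded independently (no cross-part attention), and one vector per
note is pooled as

    v = (1/n) Σᵢ mᵢ ⊙ eᵢ

summing last-hidden-state embeddings eᵢ over all parts under the
pooling mask mᵢ and dividing by the tracked content-token count n.
Two deliberate choices:

- **Start/end tokens get attention mask 1 but pooling mask 0.**
  Segmentation multiplies the number of special tokens; excluding them
  from the pool is what makes a segmented note pool to exactly the same
  vector as an unsegmented encoding of the same tokens — an identity
  the tests check for every content length up to 510.
- **Division uses the global count n, not a mean of per-part means**,
  so tokens are weighted equally regardless of how full their part is.

A single-part note therefore reduces to plain masked mean pooling.

## Path 2 — note classification

Head: dropout (0.5) → linear → sigmoid on the pooled embedding.
Training uses weighted binary cross-entropy with
pos_weight = N_neg/N_pos by default ("auto"), batch size 16, weight
decay 0.01, 4 epochs, decision threshold fixed at 0.5. 15% of the data
is held out for testing; the remaining 85% is split 80/20 into
train/validation (the internal ratio is a package choice mirroring the
pretraining split), and the epoch state with the lowest validation
loss is kept. The encoder is fine-tuned jointly with the head by
default; `freeze_encoder` trains the head on fixed pooled features.

The 3e-5 default learning rate is calibrated to fine-tuning a large
pretrained encoder. For the tiny CPU-scale profile trained from random
initialisation the package's own desk-scale runs use 1e-3 (joint) or
1e-2 (frozen head); both are plain configuration, recorded in each run
manifest.

## Path 3 — malnutrition prediction

Windows take the notes in the half-open interval
[index − 30 days, index): a note timestamped exactly 30 days before the
index date is included, one on the index date is excluded ("before
onset" excludes the onset day). Cases anchor the index at recorded
onset; for controls no anchor is defined by the problem, so the latest
note date is used (flagged as an assumption). Notes are concatenated
earliest-first.

Risk factors come from a 46-entry catalogue (factor id, canonical
name, synonyms) shipped as an editable CSV — a plausible fixture, not
a clinical standard, since the real factor list lives in prior work on
the private data. The extractor is a dictionary matcher with a
deliberately simple, pluggable negation rule: a cue ("no", "no sign
of", "denies", "without", …) ending within the five tokens preceding
the matched phrase, inside the same sentence, negates that mention; a
factor bit is 1 iff at least one non-negated mention exists. This
replaces a full entity-linking pipeline; the interface accepts any
richer extractor.

The fusion head concatenates the pooled window embedding (width d)
with the 46 risk bits and applies one fully connected layer + sigmoid.
With `use_risk_factors` off the head sees the text embedding only —
the ablation used to measure the fusion gain. Training mirrors Path 2.

## Evaluation

Stratified 5-fold cross-validation (stratification is a package choice:
at ~27% prevalence unstratified folds are fragile at small n); per-fold
precision, recall, F1, specificity, AUPRC and AUROC; arithmetic means
and two-sided 95% t-intervals (df = k−1) across folds — the CI method
is a package choice, recorded in the report. AUROC is rank-based with
midranks, identically U/(n₊·n₋); AUPRC is step-wise average precision
(trapezoidal PR interpolation is optimistic and avoided). Ratios with
zero denominators are reported as 0 with an `undefined` flag. Models
are compared fold-wise with a two-sided Mann–Whitney U test (exact
null for tie-free samples of ≤8 per group, normal approximation with
tie correction otherwise), significant iff p < 0.05 strictly; using
the k = 5 fold metrics as the samples is a presumption the comparison
report states. Baselines: bag-of-words counts and mean static word
vectors (random table by default), both scored through a logistic
regression so the comparison isolates the representation.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
with defaults fixed to the study conditions:

| parameter | default | rationale |
|---|---|---|
| female fraction | 2797/4405 ≈ 0.635 | cohort mix |
| prevalence (F/M) | 0.26 / 0.30 | sex-stratified malnutrition rates |
| mean short-note length | 64 tokens | corpus note length |
| mean 30-day window length | 644 tokens | aggregated window length |
| note cadence | derived ≈ 2.35/week | 644/64 notes per 30 days |
| length dispersion | negative binomial, r = 12 | over-dispersed like real notes; keeps a share of windows > 512 tokens |
| signal_strength | 0.8 | keyword-injection rate above baseline for malnourished clients |
| negation_rate | 0.15 | fraction of factor emissions wrapped in a negation template |

Note text is template-based (subject + action + quantity + filler,
plus aged-care shorthand such as "prn", "nbm", "obs stable"), with
malnutrition phrases defining note labels and risk-factor phrases
injected at a rate elevated by `signal_strength` for malnourished
clients. At `signal_strength = 0` the label-conditional text
distributions are identical by construction. Onset dates are placed so
at least three notes fall in the pre-onset window.

What the generator does **not** emulate: real clinical language
(vocabulary is ~100 template words), spelling noise, comorbidity
structure beyond injected phrases, inter-note dependence, or label
noise. Passing tests therefore demonstrate that the pipeline's
mechanics are correct and that it recovers a known, keyword-detectable
signal — they say nothing about performance on real nursing notes.

## Problem sizes for desk-scale runs

The test-suite and reproduction runs use: ~200–2000 synthetic clients;
pretraining 15–50 steps at batch 8 on 64–512-token chunks; note
classifiers on 400–600 notes for 4 epochs; window predictors on ~70
windows with a frozen encoder over 5 seeds. These sizes are the
package's chosen operating point for a single CPU core; every quantity
they feed is recomputed at run time from the seed.

## Known limitations

- The tiny encoder profile is orders of magnitude smaller than a
  production encoder; absolute classification scores on synthetic data
  do not transfer to real corpora.
- The negation rule is scope-window heuristics, not parsing; double
  negation and post-positioned negation ("appetite is not poor") are
  out of scope.
- The tokeniser's character fallback maps truly unseen characters to
  [UNK].
- Controls' window anchoring (latest note date) is an assumption; a
  matched-date design would remove the induced asymmetry in note
  recency.
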