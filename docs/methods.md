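# Methods

## Problem and model

A review corpus is a set of (review text, score) pairs, score ∈ {1,…,10},
collected from patients describing drug treatment, predominantly for mental
disorders. Scores are mapped to three satisfaction classes — 1–4 → 0 (poor,
urgent re-diagnosis), 5–8 → 1 (fair, monitor), 9–10 → 2 (good) — which
leaves proportions of roughly 21/28/51 %, so class imbalance and the
clinical priority of class 0 shape every design choice below.

Every classifier is treated as f = g ∘ h with encoder h ∈ H and classifier
g ∈ G. Training minimizes empirical risk, the mean per-sample loss over the
training set. The package's job is to make the members of H and G
*interchangeable*: fit any pair, pull a fitted module out of one composition
and reuse it in another.

### Encoders

**word_embedding.** Document frequencies and idf are fitted on the
normalized training corpus; the default idf is the smoothed variant
idf(t) = ln((1+N)/(1+df_t)) + 1 (an exact ln(N/df)+1 flag exists). Terms
are ranked by total tf·idf mass over the training documents and the top
k = 6000 kept (ties lexicographic). Two modes share this vocabulary:

* *tfidf_bow* (default): the selected tf·idf row, L2-normalized when
  nonzero. This is the concrete 6000-dimensional representation.
* *weighted_embedding*: v(d) = Σ_t tfidf(t,d)·e_t / Σ_t tfidf(t,d), a
  TF-IDF-weighted mean of word vectors e_t. Word vectors are supplied
  externally or fitted in-repo by truncated SVD of the term–document tf·idf
  matrix (d_w = 128 default); no canonical public embedding is assumed.

Both modes are first-class because the description of this encoder family
is genuinely ambiguous between them; the selected-TF-IDF mode is the
default since the 6000-dimension selection is operationally concrete.

**transformer.** A small bidirectional (unmasked) self-attention encoder:
word-level token ids (PAD=0, UNK=1), learned token + positional embeddings,
post-norm blocks of multi-head attention and position-wise feed-forward
with residuals, mean pooling over non-pad positions (CLS-style pooling was
considered and rejected as needless without pretraining). Defaults: 4
layers, 4 heads, d_model 128, feed-forward 256, max length 128 — small
enough to train on a CPU; tests and the acceptance script use an even
smaller instance (1 layer, d_model 16, max length 24) so the whole 6-model
matrix trains in seconds. Padding positions are excluded from attention
(additive −1e9 bias on keys) and pooling, which makes pooled vectors exactly
pad-invariant.

### Classifiers

* **rf** — bootstrap-aggregated decision trees with per-tree √d feature
  subsampling (scikit-learn backend); probabilities are tree-vote means.
  Defaults n_trees = 100, max_depth = 100 (the grid optimum).
* **svm** — one-vs-rest soft-margin SVM, linear or Gaussian kernel, C = 1,
  Gaussian bandwidth `scale` (1/(d·Var)). Decision scores are softmaxed
  into pseudo-probabilities for loss reporting only; no Platt calibration.
* **fcnn** — feed-forward net (2 hidden ReLU layers of width 64 by default,
  3-way softmax), trained by minibatch AdamW (decoupled weight decay 0.01,
  lr 1e-3, batch 32) on the focal-flooding loss, early stopping on
  validation loss (patience 10) with best-epoch parameter restore.

### Focal-flooding loss

Per sample, focal loss −α_y (1−p_y)^γ log p_y with per-class weight vector
α (the fair-satisfaction class is the one usually re-weighted) and focusing
exponent γ ≥ 0. Flooding is applied at the **batch level**:
L_FF = |mean(focal) − b| + b. Per-sample flooding was rejected because it
flips gradient signs sample-by-sample and changes the estimator
discontinuously; batch-level flooding matches the original flooding
formulation and keeps L_FF ≥ b with equality iff the batch-mean focal loss
equals b. Defaults α=(1,1,1), γ=1, b=0.125. Probabilities are clipped at
1e-12 before logs; inside the autodiff path p_y is affinely squeezed into
[1e-9, 1−1e-9] so (1−p)^γ stays differentiable at the perfect-fit limit.
Reported empirical risk on FF-trained paths is the mean *per-sample flooded*
focal loss |focal_i − b| + b, so the reported risk obeys the same floor.
Early stopping and best-epoch selection use the **unflooded** validation
focal loss: flooding regularizes the training objective, whereas model
selection should estimate validation risk.

### Training paths of the six fusions

| encoder | classifier | protocol |
|---|---|---|
| word_embedding | rf / svm | fit encoder on train, encode, fit classifier |
| word_embedding | fcnn | fit encoder, train head with FF loss + early stopping |
| transformer | fcnn | joint end-to-end training of encoder + head with FF loss |
| transformer | rf / svm | stage 1 = joint transformer+fcnn training; stage 2 = freeze encoder, encode train set, fit rf/svm |

Stage 2 never refines the encoder; recomposition across dimension
mismatches requires an explicit seeded Gaussian random-projection adapter
rather than silent truncation.

## Splits and cross-validation

Stratified 63/7/30 train/validation/test split with largest-remainder
per-class allocation (per-class deviation ≤ 1 document from exact
fractions), deterministic under seed. The corpus protocol states both a
fixed split and 10-fold cross-validation without reconciling them; this
package's interpretation, applied consistently: the 30 % test set is held
out once, 10 folds partition the remaining 70 %, each fold serves once as
the validation surface (early stopping / model choice), and each
fold-trained model is evaluated on the untouched test set; aggregates are
mean ± sd over folds.

## Preprocessing

Fixed order: emoticon glossing → chat-word expansion → grammar hook →
spelling correction → lowercase/tokenize → stop-word removal.

* Emoticon and chat-word maps are bundled package data. The exact
  dictionaries used upstream are external resources; the conversion
  *semantics* are the contract — emoticon lookup case-sensitive with
  longest-match-first, chat-word lookup whole-token case-insensitive, and
  glosses/expansions contain no map keys, making conversion idempotent.
* Grammar correction was an external web API upstream; here it is a
  pluggable no-op hook.
* Spelling correction is the unigram Norvig corrector: known words pass;
  otherwise the most frequent known candidate at Damerau edit distance 1,
  then 2, then unchanged; probability ties break lexicographically. The
  unigram model defaults to the corpus' own tokens seen ≥ 2 times.
* Tokenization lowercases and splits on non-alphanumerics; no stemming or
  lemmatization (frequency diagnostics on real corpora show inflected
  forms). Stop words default to scikit-learn's English list, flag exposed.

## Synthetic generator

Each document draws a class from proportions (0.2082, 0.2796, 0.5122), a
length from round(N(40, 15²)) truncated at ≥ 5 tokens, tokens Zipf(1.0)-
weighted from a shared pool (default 300 types, headed by realistic
review vocabulary) mixed with uniform draws from the class's disjoint
discriminative pool (default 40 types) at rate 0.3, and a score uniform in
the class's range so the label mapping inverts generation exactly. Noise
channels run per token at rate 0.05 each: emoticon insertion and slang
substitution reuse the bundled maps (so normalization can undo them — a
deliberate sharp oracle), and misspelling applies one random
delete/transpose/replace/insert, i.e. one restricted-Damerau edit.

What the generator does **not** emulate: real syntax and discourse,
context-dependent sentiment (negation, irony), label noise from subjective
scoring, and genuinely overlapping class vocabularies beyond the shared
pool. Passing tests therefore demonstrate mechanical correctness and
end-to-end recoverability of a planted signal, not clinical-grade accuracy
on real reviews; published corpus-scale metrics additionally require the
real data and large pretrained encoders and are out of scope here.

The absence of label noise has one measurable consequence for the FF loss:
on generated corpora the labels are a noise-free function of the class
lexicons, so additional fitting is always beneficial and the flood level
b = 0.125 — reached within a few epochs — caps the attainable fit. In the
imbalance comparison the focal/α re-weighting alone (b = 0) improves
minority recall over plain cross-entropy, but the full focal-flooding
configuration can end up below the cross-entropy baseline because flooding
blocks the late training phase in which minority classes are learned.
Flooding earns its keep on data noisy enough to overfit; this generator
deliberately is not, and the imbalance acceptance check documents the gap
rather than hiding it.

## Hyperparameter grids

* Focal grid: α₁ ∈ {0.5, 1, 2, 4} (classes 0 and 2 fixed at 1) × γ ∈
  {0.25, 0.5, 0.75, 1.0, 1.25, 1.5}; 24 cells, validation κ per cell, ties
  prefer larger α₁ then larger γ. All cells share one split; cell seeds are
  base seed + cell index.
* Forest grid: depth {10, 50, 100, 300} × trees {10, 20, 50, 100, 200,
  1000}; ties prefer fewer trees then smaller depth (the cheaper model).
  The encoder is fitted (or stage-1-trained) once and shared across cells.

## Evaluation

All metrics derive from one 3×3 confusion matrix (rows = true). Precision,
recall and F1 use the zero-on-zero-denominator convention, flagged in the
report. Graded F1 is Σ w_c F1_c / Σ w_c with w = (2,1,1); the aggregation
of the source metric is not printed anywhere authoritative, and the
weighted mean is the standard reading. Cohen's κ = (p_o − p_e)/(1 − p_e)
with the degenerate single-cell matrix returning 0 by convention.
Confusion matrices are reported as counts plus row-normalized rates.
Train-time is wall-clock and reported but never asserted.

## Numerical and testing choices

* All randomness flows through `numpy.random.default_rng` seeds; fits are
  bit-reproducible under a fixed seed.
* The neural stack (reverse-mode autodiff, AdamW, transformer, FCNN) is
  float64 NumPy authored in-repo; gradients are verified against central
  finite differences in the tests.
* Problem sizes in tests and the acceptance script: 200–600-document
  corpora for the model matrix and grids, 1000 documents for the 90/5/5
  imbalance comparison, 3000 for pipeline recovery, 10 000 for the
  class-share check — sizes chosen so each check is decisive at desk scale.
* Known limitations: no subword tokenization or pretraining for the
  transformer (word-level ids only), no SVM probability calibration, no
  class-weighted RF/SVM variants, no real grammar correction, English only.
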