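# Methods

## Task and model

The package classifies the relation between two gold drug mentions in
one sentence. Each candidate pair is an independent instance; the label
set is `{Advice, Effect, Mechanism, Int, Negative}` for
DDIExtraction-style corpora and
`{Pharmacokinetic, Pharmacodynamic, Unspecified, Negative}` for TAC-style
sentence-level data. `Negative` is the only negative-polarity label and
dominates real corpora by roughly 5:1 after filtering (far more before).

Three per-token representations are fused:

* **Encoder view.** A provider turns each parser word into the mean of
  its wordpiece vectors. The wordpiece sequence is truncated at
  `max_wordpieces = 128`; fully truncated words get zero rows and a
  warning rather than an error, since truncation at sentence tails is
  expected behaviour, not corruption.
* **Dependency view.** The parse tree is symmetrized (direction and
  relation type discarded — relation-typed edges are a non-goal), given
  self-loops, normalized as `Â = D̃^{-1/2}ÃD̃^{-1/2}`, and convolved by
  two ReLU GCN layers seeded with the encoder output. The symmetric
  normalization keeps `Â` symmetric with spectral radius ≤ 1, which the
  tests verify against an eigen-solver.
* **Co-occurrence view.** PMI is computed with the whole sentence as
  the window, on the *training split only* (fitting on test sentences
  would leak corpus statistics). Counting is by presence: a lemma
  appearing three times in a sentence contributes one window. Natural
  log is used; the base only rescales edge weights uniformly.
  Off-diagonal weights are `max(PMI, 0)`-style clamped: non-positive
  PMI means no association, so the edge is absent. A repeated lemma
  within a sentence is a distinct node pair whose weight uses the
  self-pair count (windows containing the lemma at least twice). Lemmas
  unseen at fit time get zero off-diagonal rows.

Per instance, drug vectors are means over the mention's token range
(discontinuous mentions use their first span, which carries the head
drug name), and verbs are tokens whose POS tag falls in the VB family
(`VB, VBD, VBG, VBN, VBP, VBZ`, configurable — taggers differ in what
they call a verb). Each aspect column concatenates the three views
(`768 + 2·200 = 1168` dims by default; the three views are concatenated
rather than projected to a common size, preserving each view's full
representation). Attentive pooling reduces the k verb columns to one
vector; the identical machinery applied to a drug's single column is a
k = 1 softmax, i.e. the identity, so the drugs and verbs share one code
path. With zero verbs the verb vector is zero, keeping shapes fixed and
making the drug-only ablation the k = 0 special case. One attention
vector `w_a` is learned per stream (drug1, drug2, verbs) rather than
shared; the streams pool different distributions.

The classifier applies dropout (p = 0.1) to the concatenated vector,
then `tanh`, then an affine map and softmax. Dropout is placed before
the `tanh` (the two orders differ only in scale statistics; one was
fixed so runs are comparable). Sentence-level pooled graph vectors are
computed and available but excluded from the classifier input by
default (`include_sentence_graph` appends them); they are redundant
with the mention/verb gathers on this architecture.

## Training

Cross-entropy is minimized with Adam at lr = 1e-4, mini-batches of 32,
10 epochs — Adam because the loss mixes dense softmax parameters with
sparse, per-instance graph-weight gradients, where per-parameter step
scaling matters. A seeded shuffle holds out 20% of instances for
validation; the epoch with the best validation micro-F1 is retained,
ties going to the earlier epoch (earlier = less overfit at equal
validation score). The encoder is frozen: only the GCN weights, the
three attention vectors and the classifier train. Fine-tuning the
encoder is out of scope; a fine-tuned provider can be plugged in behind
the same contract.

All randomness (initialization, splits, batch order, dropout masks) is
driven by explicit seeds, and the default hash-based encoder is
bit-for-bit deterministic, so two identical runs produce identical
evaluation results — a tested invariant.

## Filtering

Three surface rules remove candidate pairs that cannot interact:
identical normalized names (casefold, whitespace collapse);
abbreviation/apposition patterns, where the inter-entity text is
exactly an opening parenthesis closed right after the second mention or
one of the cues `such as, e.g., i.e., known as, called` (the cue list
is configuration — published cue lists for this step are explicitly
non-exhaustive); and coordination, where every character between the
two mentions belongs to other drug mentions, commas or `and`/`or`.
Rules apply to all labels, not only Negative, because a handful of
positive pairs in real corpora match these patterns too. Precedence
(same-name, abbreviation, coordination) is fixed so per-rule counts are
deterministic; total removal is order-independent. At evaluation time,
filtered instances are by default scored as predicted Negative — a
filtered-out positive costs recall, keeping the metric honest — with a
`drop` policy available.

## Evaluation

Micro-averaged precision, recall and F pool TP/FP/FN over the positive
classes only (detection-style scoring: a model predicting Negative
everywhere scores zero). `F = 2PR/(P+R)`, defined as 0 when `P+R = 0`.
An `all_classes` flag widens the pool for diagnostics. The
implementation is a direct confusion-matrix count and is cross-checked
in the tests against scikit-learn's micro-averaged scores on random
label vectors.

## Synthetic data

The generator emulates the statistical structure the model exploits:
two tagged drug mentions per sentence; a Negative-heavy label prior
(0.70 Negative, 0.075 for each positive class); verb lexicons that
deterministically encode the label (Mechanism: *inhibit, increase,
decrease*; Advice: *avoid, recommend, administer*; Effect: *enhance,
potentiate, prolong*; Int: *interact, combine* — the first two follow
the verb families most indicative of those relations in real DDI text,
the last two were chosen to keep the lexicons disjoint); and planted
same-name/abbreviation/coordination sentences for filter testing.
Sentences are templated, and the bundled stub parser (left-headed
chain, lexicon POS, stem lemmas) keeps drug–verb pairs within two hops
so GCN signal can flow. Per-label counts are drawn once from a seeded
multinomial; the generator returns its ground-truth plan so tests can
assert exact counts.

What passing on this data does **not** show: robustness to real
biomedical syntax, to contextual (rather than hash-based) embeddings,
to parser errors, or to the PMI distribution of a real corpus. The
synthetic corpus demonstrates that the machinery — graphs, attention,
training — is correct and can extract a planted signal, not that the
model reaches any particular score on the published benchmarks.

## Numerical choices

* Softmax and attention scores subtract their max before
  exponentiation; log-loss clamps probabilities away from zero.
* Glorot-uniform initialization throughout, seeded.
* Degenerate inputs: single-token sentences give 1×1 graphs; empty verb
  sets give zero verb vectors; an empty mention range after truncation
  yields zero vectors plus a warning.
* Backpropagation is hand-derived and verified against central finite
  differences (abs 5e-5) over every parameter tensor.

## Problem sizes

The test and acceptance runs train on 500-instance corpora (400 after
the validation split) with the default architecture (768/200 dims), ten
epochs — about 12 s per configuration on one CPU — and check the PMI
oracle on corpora of up to 50 sentences. These sizes were chosen to
make the verb→label mapping comfortably learnable while keeping the
whole suite under a minute of compute.

## Known limitations

* The shipped encoder is a deterministic hash embedding: it gives every
  word a fixed random vector, so it carries lexical identity but no
  context. Benchmark-level accuracy requires plugging in a pre-trained
  biomedical transformer behind `EncoderProvider`.
* The shipped parser stub produces a left-headed chain, not real
  syntax; `ParserProvider` is the hook for a real dependency parser.
* Coordination filtering is surface-based by contract; parse-based
  coordination detection is out of scope.
* Exact reproduction of published corpus-filtering counts depends on an
  unpublished, non-exhaustive cue list; the filter counts here are
  exact only on corpora whose patterns the configured cues cover.
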