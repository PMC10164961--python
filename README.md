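# ddimug

Multi-aspect graph relation extraction for **drug–drug interactions
(DDI)**: given a biomedical sentence with two gold-annotated drug
mentions, classify their relation into one of
`{Advice, Effect, Mechanism, Int, Negative}` (or the TAC 2018
sentence-level set `{Pharmacokinetic, Pharmacodynamic, Unspecified,
Negative}`).

The model fuses three views of each candidate pair:

1. **Contextual embeddings** — a pluggable encoder produces wordpiece
   vectors that are average-pooled into one row per parser word
   (`H0 ∈ R^{t×m1}`, default `m1 = 768`).
2. **Sentence-aspect dependency graph** — the parse tree, symmetrized
   with self-loops, convolved by a two-layer GCN
   `H^l = σ(Â H^{l-1} W^l)` with `Â = D̃^{-1/2} Ã D̃^{-1/2}` and ReLU σ
   (hidden size `m2 = 200`).
3. **Corpus-aspect co-occurrence graph** — edges weighted by positive
   point-wise mutual information computed over the training corpus with
   the whole sentence as the sliding window:

   ```
   A_ij = 1            if i = j
        = PMI(i, j)    if i ≠ j and PMI(i, j) > 0
        = 0            otherwise
   PMI(i, j) = log [ #W(i,j) · #W / (#W(i) · #W(j)) ]
   ```

   convolved by a second two-layer GCN (`m3 = 200`).

For each drug mention and each verb token, the three per-token
representations are concatenated (`768 + 200 + 200 = 1168` dims).
**Attentive pooling** — `α = softmax(w_a · tanh(A))`, `z = A α` —
reduces the variable-size verb set to one vector; the concatenation
`[z_drug1; z_drug2; z_verbs]` passes through dropout, `tanh` and a
softmax classifier. Micro-averaged P/R/F over the four positive classes
is the evaluation metric, and three preprocessing rules remove candidate
pairs that trivially cannot interact (same drug name, abbreviation
patterns like "DRUG-A (DRUG-B)", coordinate lists "DRUG-A, …, DRUG-B").

The network, its gradients and Adam are implemented in NumPy; encoders
and dependency parsers sit behind provider contracts with deterministic
offline stubs, so the entire stack runs on one CPU with no downloads.

## Worked example

```python
from ddimug import GeneratorConfig, generate_corpus, apply_filters, train
from ddimug.pipeline import TrainConfig

corpus = generate_corpus(GeneratorConfig(n_sentences=500, seed=3))
kept = apply_filters(corpus.instances).kept
result = train(kept, TrainConfig(seed=3))
print(f"best epoch: {result.best_epoch}")
print(f"training micro-F1: {result.training_eval().micro_f1:.3f}")
```

prints

```
best epoch: 9
training micro-F1: 1.000
```

The generator plants class-predictive verbs (e.g. *inhibit/increase/
decrease* → Mechanism, *avoid/recommend/administer* → Advice) under a
Negative-heavy label prior, so a training micro-F1 near 1 shows the
network recovers the verb→label mapping through the full
encoder-graph-attention stack. The same API evaluates held-out data
(`ddimug.pipeline.evaluate`) and exports per-instance explanations
(`ddimug.pipeline.explain`): dependency edges, positive-PMI edges and
the attention weight each verb received.

A CLI mirrors the library:

```bash
ddimug stats --data corpus.jsonl
ddimug train --config run.yaml
ddimug eval --weights runs/model --data test.jsonl
ddimug explain --weights runs/model --data test.jsonl --instance s7.p0
ddimug build-graphs --data corpus.jsonl --out pmi.json
```

Corpora are read from the SemEval-2013 Task 9 XML dialect
(`read_semeval_xml`) or a generic JSONL format (`read_jsonl`).

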