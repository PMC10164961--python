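"""Graph construction: corpus PMI statistics and per-sentence adjacency.

Two weighted graphs over sentence tokens feed the GCNs:

* **dependency** — symmetrized 0/1 edges of the sentence's parse tree,
  plus self-loops;
* **co-occurrence** — off-diagonal weights are positive point-wise mutual
  information values computed over the whole training corpus with the
  sentence as the sliding window, clamped to 0 when PMI <= 0:

      A[i][j] = 1                      if i == j
              = PMI(i, j)              if i != j and PMI(i, j) > 0
              = 0                      otherwise

  PMI(i, j) = log( p(i,j) / (p(i) p(j)) ) with p(i,j) = #W(i,j)/#W and
  p(i) = #W(i)/#W, where #W is the number of sentences (windows), #W(i)
  the number of sentences containing lemma i at least once, and #W(i,j)
  the number containing both. Natural log; the base only rescales weights.

Both graphs are normalized for GCN use as A_hat = D^-1/2 (A) D^-1/2 where
A already includes self-loops and D is its degree matrix.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from ddimug.linguistic import ROOT, ParsedSentence

NEG_INF = float("-inf")


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class PmiTable:
    """Sparse corpus-level window counts supporting PMI queries.

    ``pair_window_counts`` keys are sorted lemma pairs; the pair
    ``(w, w)`` counts sentences containing lemma ``w`` at least twice,
    kept distinct so repeated lemmas within one sentence can be weighted.
    """

    vocab: dict = field(default_factory=dict)  # lemma -> index
    window_count_total: int = 0  # number of windows (#W)
    word_window_counts: dict = field(default_factory=dict)  # lemma -> #W(i)
    pair_window_counts: dict = field(default_factory=dict)  # (a,b) -> #W(i,j)

    def to_json(self, path) -> None:
        obj = {
            "window_count_total": self.window_count_total,
            "word_window_counts": self.word_window_counts,
            "pair_window_counts": [
                [a, b, c] for (a, b), c in sorted(self.pair_window_counts.items())
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, ensure_ascii=False)

    @classmethod
    def from_json(cls, path) -> "PmiTable":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        table = cls(
            window_count_total=obj["window_count_total"],
            word_window_counts=dict(obj["word_window_counts"]),
            pair_window_counts={
                (a, b): c for a, b, c in obj["pair_window_counts"]
            },
        )
        table.vocab = {w: i for i, w in enumerate(sorted(table.word_window_counts))}
        return table


def fit_pmi(parsed_sentences) -> PmiTable:
    """Count presence windows over the (training) sentences.

    Counting is by presence, not frequency: a lemma occurring three times
    in one sentence contributes one to its window count. The self-pair
    ``(w, w)`` is counted only for sentences containing ``w`` twice.
    """
    sentences = list(parsed_sentences)
    if not sentences:
        raise ValueError("fit_pmi requires at least one sentence")
    table = PmiTable(window_count_total=len(sentences))
    for parsed in sentences:
        lemmas = parsed.lemmas() if isinstance(parsed, ParsedSentence) else list(parsed)
        counts: dict[str, int] = {}
        for lem in lemmas:
            counts[lem] = counts.get(lem, 0) + 1
        present = sorted(counts)
        for lem in present:
            table.word_window_counts[lem] = table.word_window_counts.get(lem, 0) + 1
            if counts[lem] >= 2:
                k = (lem, lem)
                table.pair_window_counts[k] = table.pair_window_counts.get(k, 0) + 1
        for i, a in enumerate(present):
            for b in present[i + 1 :]:
                k = (a, b)
                table.pair_window_counts[k] = table.pair_window_counts.get(k, 0) + 1
    table.vocab = {w: i for i, w in enumerate(sorted(table.word_window_counts))}
    return table


def pmi(table: PmiTable, i: str, j: str) -> float:
    """PMI(i, j) in natural log; -inf when the pair never co-occurs."""
    for lemma in (i, j):
        if lemma not in table.word_window_counts:
            raise KeyError(f"lemma {lemma!r} not in PMI vocabulary")
    joint = table.pair_window_counts.get(_key(i, j), 0)
    if joint == 0:
        return NEG_INF
    return math.log(
        joint * table.window_count_total
        / (table.word_window_counts[i] * table.word_window_counts[j])
    )


def pmi_from_counts(joint: int, count_i: int, count_j: int, total: int) -> float:
    """PMI directly from window counts (natural log)."""
    if joint == 0:
        return NEG_INF
    return math.log(joint * total / (count_i * count_j))


@dataclass
class AdjacencyMatrix:
    weights: np.ndarray  # square, symmetric, non-negative
    kind: str  # "dependency" | "cooccurrence"
    normalized: bool = False

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Upper-triangle nonzero off-diagonal entries as (i, j, w)."""
        out = []
        w = self.weights
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if w[i, j] != 0.0:
                    out.append((i, j, float(w[i, j])))
        return out


def build_dependency_adjacency(parsed: ParsedSentence) -> AdjacencyMatrix:
    """Symmetrized parse-tree adjacency with self-loops (A + I)."""
    n = len(parsed.tokens)
    A = np.eye(n)
    for e in parsed.edges:
        if e.head == ROOT:
            continue
        A[e.head, e.dependent] = 1.0
        A[e.dependent, e.head] = 1.0
    return AdjacencyMatrix(weights=A, kind="dependency")


def build_cooccurrence_adjacency(
    parsed: ParsedSentence, table: PmiTable
) -> AdjacencyMatrix:
    """Subgraph of the corpus co-occurrence graph induced on the sentence.

    Nodes are the sentence tokens; the weight between two tokens is the
    positive PMI of their lemma pair, 0 for PMI <= 0 or lemmas unseen at
    fit time. Diagonal is 1.
    """
    lemmas = parsed.lemmas()
    n = len(lemmas)
    A = np.eye(n)
    for i in range(n):
        if lemmas[i] not in table.word_window_counts:
            continue
        for j in range(i + 1, n):
            if lemmas[j] not in table.word_window_counts:
                continue
            value = pmi(table, lemmas[i], lemmas[j])
            if value > 0.0 and math.isfinite(value):
                A[i, j] = A[j, i] = value
    return AdjacencyMatrix(weights=A, kind="cooccurrence")


def normalize_adjacency(adj: AdjacencyMatrix) -> AdjacencyMatrix:
    """Symmetric GCN normalization A_hat = D^-1/2 A D^-1/2.

    Requires self-loops already present (diagonal >= 1), which guarantees
    strictly positive degrees.
    """
    A = adj.weights
    if A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency not square: {A.shape}")
    if np.any(np.diag(A) < 1.0):
        raise ValueError("adjacency missing self-loops (diagonal < 1)")
    deg = A.sum(axis=1)
    assert np.all(deg > 0), "zero-degree row despite self-loops"
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    A_hat = A * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return AdjacencyMatrix(weights=A_hat, kind=adj.kind, normalized=True)
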