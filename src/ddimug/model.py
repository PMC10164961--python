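"""The multi-aspect graph network for DDI classification.

Per instance, three views of the sentence are combined:

* the contextual word matrix from a pluggable encoder (wordpiece vectors
  average-pooled into parser-word rows),
* a two-layer GCN over the normalized dependency-parse adjacency,
* a two-layer GCN over the normalized PMI co-occurrence adjacency,

with each GCN seeded by the encoder output as initial node features
(``H^l = sigma(A_hat H^{l-1} W^l)``, ReLU nonlinearity). For each drug
mention and each verb token, the three per-token representations are
concatenated into an aspect vector of size ``encoder_dim + 2*gcn_hidden``.
Attentive pooling (``alpha = softmax(w_a tanh(A))``, ``z = A alpha``)
reduces the variable-size verb set to one vector; the same machinery is
applied to each drug's single column, where it degenerates to identity.
The concatenation ``[z_drug1; z_drug2; z_verbs]`` passes through dropout,
tanh and a softmax classifier.

The network, its gradients and the Adam optimizer are implemented
directly in NumPy: model sizes here are small enough that explicit
backpropagation on dense arrays is both fast on one CPU and exactly
reproducible. Encoders are provider objects; the default is a
deterministic hash-based embedding, which keeps the whole stack
runnable offline (a fine-tuned transformer provider can be dropped in
behind the same contract).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ddimug.corpus_io import DDI_LABELS, PairInstance
from ddimug.graphs import (
    AdjacencyMatrix,
    PmiTable,
    build_cooccurrence_adjacency,
    build_dependency_adjacency,
    normalize_adjacency,
)
from ddimug.linguistic import ParsedSentence


# --------------------------------------------------------------------------
# configuration

@dataclass
class ModelConfig:
    encoder_name: str = "hash-stub"
    encoder_dim: int = 768
    gcn_hidden: int = 200
    max_wordpieces: int = 128
    dropout: float = 0.1
    labels: tuple = DDI_LABELS
    verb_tag_set: tuple = ("VB", "VBD", "VBG", "VBN", "VBP", "VBZ")
    seed: int = 0
    # ablation switches (the full model uses all three aspects)
    use_dep_graph: bool = True
    use_word_graph: bool = True
    use_verbs: bool = True
    # sentence-level pooled graph vectors are computed but not fed to the
    # classifier unless this flag is set
    include_sentence_graph: bool = False

    def __post_init__(self):
        if self.encoder_dim <= 0 or self.gcn_hidden <= 0:
            raise ValueError("dimensions must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def num_classes(self) -> int:
        return len(self.labels)

    @property
    def aspect_dim(self) -> int:
        """Dimension of one concatenated [pub; dep; word] column."""
        return self.encoder_dim + 2 * self.gcn_hidden

    @property
    def total_dim(self) -> int:
        d = 3 * self.aspect_dim
        if self.include_sentence_graph:
            d += 2 * self.gcn_hidden
        return d


# --------------------------------------------------------------------------
# encoder providers

class EncoderProvider:
    """Contract: deterministic wordpiece tokenization + piece vectors."""

    name = "abstract"
    dim: int

    def wordpieces(self, surface: str) -> list[str]:
        raise NotImplementedError

    def piece_vector(self, piece: str) -> np.ndarray:
        raise NotImplementedError


class HashEncoderProvider(EncoderProvider):
    """Deterministic hash-based embeddings for offline runs.

    Each wordpiece maps, via a BLAKE2 digest of its lowercased string, to
    a fixed standard-normal vector; words longer than ``piece_len`` are
    split into several pieces so that the word-level average pooling is
    exercised. Bit-for-bit reproducible across processes.
    """

    name = "hash-stub"

    def __init__(self, dim: int = 768, piece_len: int = 4):
        self.dim = dim
        self.piece_len = piece_len
        self._cache: dict[str, np.ndarray] = {}

    def wordpieces(self, surface: str) -> list[str]:
        s = surface.lower()
        if len(s) <= self.piece_len:
            return [s]
        return [s[i : i + self.piece_len] for i in range(0, len(s), self.piece_len)]

    def piece_vector(self, piece: str) -> np.ndarray:
        vec = self._cache.get(piece)
        if vec is None:
            digest = hashlib.blake2b(piece.encode("utf-8"), digest_size=8).digest()
            seed = int.from_bytes(digest, "big") % (2**31)
            vec = np.random.default_rng(seed).standard_normal(self.dim)
            self._cache[piece] = vec
        return vec


ENCODERS: dict[str, type[EncoderProvider]] = {"hash-stub": HashEncoderProvider}


def get_encoder(config: ModelConfig) -> EncoderProvider:
    try:
        cls = ENCODERS[config.encoder_name]
    except KeyError as exc:
        raise KeyError(
            f"unknown encoder {config.encoder_name!r}; registered: {sorted(ENCODERS)}"
        ) from exc
    return cls(dim=config.encoder_dim)


def encode_words(tokens, encoder: EncoderProvider, config: ModelConfig) -> np.ndarray:
    """Word-level embedding matrix (t x encoder_dim).

    Row i is the mean of token i's wordpiece vectors. The wordpiece
    sequence is truncated at ``max_wordpieces``; a token whose pieces are
    all truncated away gets a zero row and triggers a warning.
    """
    H = np.zeros((len(tokens), encoder.dim))
    budget = config.max_wordpieces
    used = 0
    truncated = []
    for i, tok in enumerate(tokens):
        pieces = encoder.wordpieces(tok.surface)
        take = pieces[: max(0, budget - used)]
        used += len(pieces)
        if not take:
            truncated.append(tok.surface)
            continue
        H[i] = np.mean([encoder.piece_vector(p) for p in take], axis=0)
    if truncated:
        warnings.warn(
            f"{len(truncated)} token(s) fully truncated at {budget} wordpieces; "
            "their rows are zero",
            stacklevel=2,
        )
    return H


# --------------------------------------------------------------------------
# functional pieces

def gcn_layer(H: np.ndarray, A_hat: np.ndarray, W: np.ndarray, sigma=None) -> np.ndarray:
    """One graph-convolution layer ``sigma(A_hat H W)`` (no mutation)."""
    if H.shape[0] != A_hat.shape[0] or H.shape[1] != W.shape[0]:
        raise ValueError(
            f"shape mismatch: A_hat {A_hat.shape}, H {H.shape}, W {W.shape}"
        )
    out = A_hat @ H @ W
    return out if sigma is None else sigma(out)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def gcn_forward(H0: np.ndarray, A_hat: np.ndarray, W1: np.ndarray, W2: np.ndarray):
    """Two ReLU GCN layers; returns intermediates for backprop."""
    AH0 = A_hat @ H0
    P1 = AH0 @ W1
    M1 = relu(P1)
    AM1 = A_hat @ M1
    P2 = AM1 @ W2
    M2 = relu(P2)
    return {"AH0": AH0, "P1": P1, "M1": M1, "AM1": AM1, "P2": P2, "M2": M2}


def average_pool_nodes(node_reps: np.ndarray) -> np.ndarray:
    """Mean over node rows (the sentence-level graph vector)."""
    if node_reps.shape[0] == 0:
        raise ValueError("cannot pool zero nodes")
    return node_reps.mean(axis=0)


def attentive_pool(columns: np.ndarray, w_a: np.ndarray):
    """Softmax-attention pooling over the columns of a (d x k) matrix.

    ``scores_j = w_a . tanh(col_j)``; ``alpha = softmax(scores)``;
    output ``z = sum_j alpha_j col_j``. Requires k >= 1 (callers
    substitute a zero vector for empty column sets).
    """
    if columns.ndim != 2 or columns.shape[1] < 1:
        raise ValueError(f"need a (d, k>=1) column matrix, got {columns.shape}")
    T = np.tanh(columns)
    scores = w_a @ T
    scores = scores - scores.max()
    exps = np.exp(scores)
    alpha = exps / exps.sum()
    z = columns @ alpha
    return z, alpha


def softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


@dataclass
class AspectBundle:
    """Per-instance aspect representations of drug1, drug2 and verbs."""

    drug1_pub: np.ndarray
    drug2_pub: np.ndarray
    verbs_pub: np.ndarray  # (k, encoder_dim)
    drug1_dep: np.ndarray
    drug2_dep: np.ndarray
    verbs_dep: np.ndarray  # (k, gcn_hidden)
    drug1_word: np.ndarray
    drug2_word: np.ndarray
    verbs_word: np.ndarray  # (k, gcn_hidden)

    @property
    def k(self) -> int:
        return self.verbs_pub.shape[0]


def _mention_mean(matrix: np.ndarray, span: tuple[int, int]) -> np.ndarray:
    lo, hi = span
    lo, hi = max(lo, 0), min(hi, matrix.shape[0])
    if hi <= lo:
        warnings.warn("mention token range empty after truncation; using zeros",
                      stacklevel=3)
        return np.zeros(matrix.shape[1])
    return matrix[lo:hi].mean(axis=0)


def gather_aspects(
    encoder_out: np.ndarray,
    dep_nodes: np.ndarray,
    word_nodes: np.ndarray,
    parsed: ParsedSentence,
    instance: PairInstance,
) -> AspectBundle:
    """Extract drug and verb rows from the three representation matrices.

    Drug vectors are means over the mention's token range; verb matrices
    stack the rows at the sentence's verb indices (k may be 0).
    """
    span1 = parsed.mention_token_spans[instance.e1_id]
    span2 = parsed.mention_token_spans[instance.e2_id]
    verbs = [v for v in parsed.verb_indices if v < encoder_out.shape[0]]
    return AspectBundle(
        drug1_pub=_mention_mean(encoder_out, span1),
        drug2_pub=_mention_mean(encoder_out, span2),
        verbs_pub=encoder_out[verbs] if verbs else np.zeros((0, encoder_out.shape[1])),
        drug1_dep=_mention_mean(dep_nodes, span1),
        drug2_dep=_mention_mean(dep_nodes, span2),
        verbs_dep=dep_nodes[verbs] if verbs else np.zeros((0, dep_nodes.shape[1])),
        drug1_word=_mention_mean(word_nodes, span1),
        drug2_word=_mention_mean(word_nodes, span2),
        verbs_word=word_nodes[verbs] if verbs else np.zeros((0, word_nodes.shape[1])),
    )


# --------------------------------------------------------------------------
# prepared instances (encoder output and graphs are fixed during training)

@dataclass
class PreparedInstance:
    instance_id: str
    H0: np.ndarray  # (t, encoder_dim)
    A_dep: np.ndarray  # normalized (t, t)
    A_word: np.ndarray  # normalized (t, t)
    span1: tuple[int, int]
    span2: tuple[int, int]
    verb_indices: list[int]
    label_index: int
    parsed: ParsedSentence | None = None
    dep_adj_raw: AdjacencyMatrix | None = None
    word_adj_raw: AdjacencyMatrix | None = None


def prepare_instance(
    instance: PairInstance,
    parsed: ParsedSentence,
    table: PmiTable,
    encoder: EncoderProvider,
    config: ModelConfig,
) -> PreparedInstance:
    """Precompute everything the network consumes for one instance."""
    try:
        H0 = encode_words(parsed.tokens, encoder, config)
    except Exception as exc:
        raise RuntimeError(
            f"encoding failed for sentence {parsed.sentence_id}: {exc}"
        ) from exc
    dep_raw = build_dependency_adjacency(parsed)
    word_raw = build_cooccurrence_adjacency(parsed, table)
    verbs = list(parsed.verb_indices) if config.use_verbs else []
    return PreparedInstance(
        instance_id=instance.instance_id,
        H0=H0,
        A_dep=normalize_adjacency(dep_raw).weights,
        A_word=normalize_adjacency(word_raw).weights,
        span1=parsed.mention_token_spans[instance.e1_id],
        span2=parsed.mention_token_spans[instance.e2_id],
        verb_indices=verbs,
        label_index=config.labels.index(instance.label),
        parsed=parsed,
        dep_adj_raw=dep_raw,
        word_adj_raw=word_raw,
    )


# --------------------------------------------------------------------------
# the model

_PARAM_NAMES = (
    "W1_dep", "W2_dep", "W1_word", "W2_word",
    "wa_drug1", "wa_drug2", "wa_verbs", "W_s", "b_s",
)


class DDIMuGModel:
    """Weights + forward/backward for the multi-aspect graph network."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        De, Dg, D, Z, C = (
            config.encoder_dim,
            config.gcn_hidden,
            config.aspect_dim,
            config.total_dim,
            config.num_classes,
        )

        def glorot(fan_in, fan_out):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_in, fan_out))

        self.params: dict[str, np.ndarray] = {
            "W1_dep": glorot(De, Dg),
            "W2_dep": glorot(Dg, Dg),
            "W1_word": glorot(De, Dg),
            "W2_word": glorot(Dg, Dg),
            "wa_drug1": glorot(D, 1)[:, 0],
            "wa_drug2": glorot(D, 1)[:, 0],
            "wa_verbs": glorot(D, 1)[:, 0],
            "W_s": np.ascontiguousarray(glorot(Z, C).T),
            "b_s": np.zeros(C),
        }

    # -- forward -----------------------------------------------------------

    def _node_representations(self, prep: PreparedInstance):
        cfg = self.config
        t = prep.H0.shape[0]
        zeros = np.zeros((t, cfg.gcn_hidden))
        dep_cache = word_cache = None
        if cfg.use_dep_graph:
            dep_cache = gcn_forward(
                prep.H0, prep.A_dep, self.params["W1_dep"], self.params["W2_dep"]
            )
        if cfg.use_word_graph:
            word_cache = gcn_forward(
                prep.H0, prep.A_word, self.params["W1_word"], self.params["W2_word"]
            )
        M2 = dep_cache["M2"] if dep_cache else zeros
        N2 = word_cache["M2"] if word_cache else zeros
        return M2, N2, dep_cache, word_cache

    def _columns(self, prep: PreparedInstance, M2, N2):
        """Assemble the drug columns (d, 1) and verb columns (d, k)."""
        H0 = prep.H0

        def drug_col(span):
            return np.concatenate(
                [_mention_mean(H0, span), _mention_mean(M2, span), _mention_mean(N2, span)]
            )[:, None]

        c1, c2 = drug_col(prep.span1), drug_col(prep.span2)
        verbs = prep.verb_indices
        if verbs:
            Cv = np.concatenate([H0[verbs].T, M2[verbs].T, N2[verbs].T], axis=0)
        else:
            Cv = np.zeros((self.config.aspect_dim, 0))
        return c1, c2, Cv

    def forward(
        self,
        prep: PreparedInstance,
        train_mode: bool = False,
        dropout_rng: np.random.Generator | None = None,
        want_cache: bool = False,
    ):
        """Class probabilities for one instance (optionally with cache)."""
        cfg = self.config
        p = self.params
        M2, N2, dep_cache, word_cache = self._node_representations(prep)
        c1, c2, Cv = self._columns(prep, M2, N2)
        z1, a1 = attentive_pool(c1, p["wa_drug1"])
        z2, a2 = attentive_pool(c2, p["wa_drug2"])
        if Cv.shape[1] > 0:
            zv, av = attentive_pool(Cv, p["wa_verbs"])
        else:
            zv, av = np.zeros(cfg.aspect_dim), np.zeros(0)
        parts = [z1, z2, zv]
        if cfg.include_sentence_graph:
            parts += [average_pool_nodes(M2), average_pool_nodes(N2)]
        z_total = np.concatenate(parts)

        if train_mode and cfg.dropout > 0.0:
            if dropout_rng is None:
                raise ValueError("train_mode requires a dropout rng")
            keep = 1.0 - cfg.dropout
            mask = (dropout_rng.random(z_total.shape) < keep) / keep
        else:
            mask = np.ones_like(z_total)
        z_drop = z_total * mask
        h = np.tanh(z_drop)
        logits = p["W_s"] @ h + p["b_s"]
        probs = softmax(logits)
        if not np.all(np.isfinite(probs)):
            raise FloatingPointError(
                f"non-finite activations for instance {prep.instance_id}"
            )
        if not want_cache:
            return probs
        cache = {
            "M2": M2, "N2": N2, "dep": dep_cache, "word": word_cache,
            "c1": c1, "c2": c2, "Cv": Cv,
            "a1": a1, "a2": a2, "av": av,
            "z_total": z_total, "mask": mask, "h": h, "probs": probs,
        }
        return probs, cache

    def predict(self, prep: PreparedInstance) -> int:
        return int(np.argmax(self.forward(prep)))

    def verb_attention(self, prep: PreparedInstance) -> np.ndarray:
        _, cache = self.forward(prep, want_cache=True)
        return cache["av"]

    # -- backward ----------------------------------------------------------

    def loss_and_grads(
        self,
        prep: PreparedInstance,
        train_mode: bool = True,
        dropout_rng: np.random.Generator | None = None,
    ):
        """Cross-entropy loss and parameter gradients for one instance."""
        cfg = self.config
        p = self.params
        probs, cache = self.forward(
            prep, train_mode=train_mode, dropout_rng=dropout_rng, want_cache=True
        )
        y = prep.label_index
        loss = -float(np.log(max(probs[y], 1e-300)))
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        dlogits = probs.copy()
        dlogits[y] -= 1.0
        grads["W_s"] += np.outer(dlogits, cache["h"])
        grads["b_s"] += dlogits
        dh = p["W_s"].T @ dlogits
        dz_drop = dh * (1.0 - cache["h"] ** 2)
        dz_total = dz_drop * cache["mask"]

        D = cfg.aspect_dim
        dz1, dz2, dzv = dz_total[:D], dz_total[D : 2 * D], dz_total[2 * D : 3 * D]

        t = prep.H0.shape[0]
        dM2 = np.zeros((t, cfg.gcn_hidden))
        dN2 = np.zeros((t, cfg.gcn_hidden))
        if cfg.include_sentence_graph:
            Dg = cfg.gcn_hidden
            dGdep = dz_total[3 * D : 3 * D + Dg]
            dGword = dz_total[3 * D + Dg :]
            dM2 += dGdep[None, :] / t
            dN2 += dGword[None, :] / t

        def pool_backward(columns, alpha, w_name, dz):
            """Backprop through attentive_pool; returns dColumns."""
            T = np.tanh(columns)
            dalpha = columns.T @ dz
            dC = np.outer(dz, alpha)
            ds = alpha * (dalpha - alpha @ dalpha)
            grads[w_name] += T @ ds
            dC += p[w_name][:, None] * (1.0 - T**2) * ds[None, :]
            return dC

        def scatter_drug(dcol, span):
            """Split a drug column gradient into the dep/word node matrices."""
            lo, hi = span
            m = hi - lo
            if m <= 0:
                return
            De = cfg.encoder_dim
            ddep = dcol[De : De + cfg.gcn_hidden]
            dword = dcol[De + cfg.gcn_hidden :]
            dM2[lo:hi] += ddep[None, :] / m
            dN2[lo:hi] += dword[None, :] / m

        dc1 = pool_backward(cache["c1"], cache["a1"], "wa_drug1", dz1)
        dc2 = pool_backward(cache["c2"], cache["a2"], "wa_drug2", dz2)
        scatter_drug(dc1[:, 0], prep.span1)
        scatter_drug(dc2[:, 0], prep.span2)
        if cache["Cv"].shape[1] > 0:
            dCv = pool_backward(cache["Cv"], cache["av"], "wa_verbs", dzv)
            De = cfg.encoder_dim
            for j, v in enumerate(prep.verb_indices):
                dM2[v] += dCv[De : De + cfg.gcn_hidden, j]
                dN2[v] += dCv[De + cfg.gcn_hidden :, j]

        def gcn_backward(gcache, A_hat, dOut, w1_name, w2_name):
            dP2 = dOut * (gcache["P2"] > 0)
            grads[w2_name] += gcache["AM1"].T @ dP2
            dM1 = A_hat @ dP2 @ p[w2_name].T  # A_hat symmetric
            dP1 = dM1 * (gcache["P1"] > 0)
            grads[w1_name] += gcache["AH0"].T @ dP1

        if cache["dep"] is not None:
            gcn_backward(cache["dep"], prep.A_dep, dM2, "W1_dep", "W2_dep")
        if cache["word"] is not None:
            gcn_backward(cache["word"], prep.A_word, dN2, "W1_word", "W2_word")
        return loss, grads

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Write weights (.npz) and config (.json) into a directory."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.params)
        cfg = asdict(self.config)
        cfg["labels"] = list(self.config.labels)
        with open(path / "config.json", "w", encoding="utf-8") as fh:
            json.dump(cfg, fh, indent=1)

    @classmethod
    def load(cls, path) -> "DDIMuGModel":
        path = Path(path)
        with open(path / "config.json", encoding="utf-8") as fh:
            cfg = json.load(fh)
        cfg["labels"] = tuple(cfg["labels"])
        model = cls(ModelConfig(**cfg))
        with np.load(path / "weights.npz") as data:
            for name in _PARAM_NAMES:
                model.params[name] = data[name]
        return model


class Adam:
    """Adam optimizer over the model's parameter dict."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / b1t
            v_hat = self.v[k] / b2t
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
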