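"""Training, evaluation and explanation for the DDI classifier.

Evaluation follows the detection-style convention of the DDI task:
micro-averaged precision/recall/F pool TP/FP/FN over the positive
relation classes only, so a system predicting Negative everywhere scores
zero. A diagnostic flag widens the pool to all classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ddimug.corpus_io import NEGATIVE_LABEL, PairInstance, positive_labels
from ddimug.filtering import FilterPolicy, apply_filters
from ddimug.graphs import PmiTable, fit_pmi
from ddimug.linguistic import ParserProvider, StubParserProvider, parse
from ddimug.model import (
    Adam,
    DDIMuGModel,
    ModelConfig,
    PreparedInstance,
    get_encoder,
    prepare_instance,
)


# --------------------------------------------------------------------------
# metrics

@dataclass
class ClassScores:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int


@dataclass
class EvalResult:
    per_class: dict  # label -> ClassScores
    micro: ClassScores
    confusion: np.ndarray  # gold x predicted counts
    labels: tuple
    policy: str = "score"

    @property
    def micro_f1(self) -> float:
        return self.micro.f1


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def micro_prf(gold, predicted, positive_labels=None, labels=None,
              all_classes: bool = False) -> EvalResult:
    """Micro-averaged P/R/F with per-class breakdown.

    TP is a positive instance classified as its own positive class; FP
    counts predictions of a positive class whose gold label differs; FN
    counts positive-gold instances not recovered. Micro pools the counts
    over ``positive_labels`` (all labels if ``all_classes``).
    """
    gold, predicted = list(gold), list(predicted)
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted must have equal length")
    if labels is None:
        labels = tuple(sorted(set(gold) | set(predicted)))
    index = {l: i for i, l in enumerate(labels)}
    for lab in gold + predicted:
        if lab not in index:
            raise ValueError(f"unknown label {lab!r}")
    if positive_labels is None:
        positive_labels = tuple(l for l in labels if l != NEGATIVE_LABEL)
    confusion = np.zeros((len(labels), len(labels)), dtype=int)
    for g, p in zip(gold, predicted):
        confusion[index[g], index[p]] += 1
    per_class = {}
    for lab in labels:
        i = index[lab]
        tp = int(confusion[i, i])
        fp = int(confusion[:, i].sum() - tp)
        fn = int(confusion[i, :].sum() - tp)
        pr, rc, f1 = _prf(tp, fp, fn)
        per_class[lab] = ClassScores(pr, rc, f1, tp, fp, fn)
    pool = labels if all_classes else positive_labels
    tp = sum(per_class[l].tp for l in pool)
    fp = sum(per_class[l].fp for l in pool)
    fn = sum(per_class[l].fn for l in pool)
    pr, rc, f1 = _prf(tp, fp, fn)
    return EvalResult(
        per_class=per_class,
        micro=ClassScores(pr, rc, f1, tp, fp, fn),
        confusion=confusion,
        labels=labels,
    )


# --------------------------------------------------------------------------
# training

@dataclass
class TrainConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    batch_size: int = 32
    epochs: int = 10
    lr: float = 1e-4
    val_fraction: float = 0.2
    seed: int = 0


@dataclass
class EpochLog:
    epoch: int
    mean_loss: float
    val_micro_f1: float


@dataclass
class TrainResult:
    model: DDIMuGModel
    pmi_table: PmiTable
    log: list
    best_epoch: int
    parses: dict  # sentence_id -> ParsedSentence
    train_instances: list = field(default_factory=list)
    val_instances: list = field(default_factory=list)

    def training_eval(self) -> EvalResult:
        """Micro P/R/F of the retained weights on the training split."""
        preps = prepare_all(self.train_instances, self.parses, self.pmi_table, self.model)
        pred = _predict_labels(self.model, preps)
        gold = [i.label for i in self.train_instances]
        return micro_prf(gold, pred, labels=self.model.config.labels)


def _parse_all(instances, provider: ParserProvider, verb_tags):
    parses = {}
    for inst in instances:
        sid = inst.sentence.sentence_id
        if sid not in parses:
            parses[sid] = parse(inst.sentence, provider, verb_tags)
    return parses


def prepare_all(instances, parses, table, model: DDIMuGModel):
    encoder = get_encoder(model.config)
    return [
        prepare_instance(
            inst, parses[inst.sentence.sentence_id], table, encoder, model.config
        )
        for inst in instances
    ]


def _predict_labels(model: DDIMuGModel, preps) -> list[str]:
    labels = model.config.labels
    return [labels[model.predict(p)] for p in preps]


def train(
    instances,
    config: TrainConfig | None = None,
    provider: ParserProvider | None = None,
) -> TrainResult:
    """Train the network on labelled pair instances.

    A seeded shuffle holds out ``val_fraction`` of the instances for
    validation; PMI statistics are fitted on the training portion only.
    Mini-batch cross-entropy is minimized with Adam; the weights of the
    epoch with the best validation micro-F1 are retained (ties broken by
    the earlier epoch).
    """
    config = config or TrainConfig()
    instances = list(instances)
    if not instances:
        raise ValueError("no training instances")
    provider = provider or StubParserProvider()
    rng = np.random.default_rng(config.seed)

    order = rng.permutation(len(instances))
    n_val = int(round(config.val_fraction * len(instances)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    train_insts = [instances[i] for i in train_idx]
    val_insts = [instances[i] for i in val_idx]
    if not train_insts:
        raise ValueError("training split is empty")

    parses = _parse_all(instances, provider, frozenset(config.model.verb_tag_set))
    table = fit_pmi([parses[i.sentence.sentence_id] for i in train_insts])

    model = DDIMuGModel(config.model)
    train_preps = prepare_all(train_insts, parses, table, model)
    val_preps = prepare_all(val_insts, parses, table, model)
    val_gold = [i.label for i in val_insts]

    optimizer = Adam(model.params, lr=config.lr)
    dropout_rng = np.random.default_rng(config.seed + 1)
    pos = positive_labels(config.model.labels)

    best_f1, best_epoch = -1.0, -1
    best_params = {k: v.copy() for k, v in model.params.items()}
    log: list[EpochLog] = []
    for epoch in range(config.epochs):
        perm = rng.permutation(len(train_preps))
        losses = []
        for start in range(0, len(perm), config.batch_size):
            batch = perm[start : start + config.batch_size]
            total = {k: np.zeros_like(v) for k, v in model.params.items()}
            for idx in batch:
                loss, grads = model.loss_and_grads(
                    train_preps[idx], train_mode=True, dropout_rng=dropout_rng
                )
                losses.append(loss)
                for k in total:
                    total[k] += grads[k]
            for k in total:
                total[k] /= len(batch)
            optimizer.step(model.params, total)
        if val_preps:
            val_pred = _predict_labels(model, val_preps)
            val_f1 = micro_prf(
                val_gold, val_pred, positive_labels=pos, labels=config.model.labels
            ).micro_f1
        else:
            val_f1 = 0.0
        log.append(EpochLog(epoch, float(np.mean(losses)), val_f1))
        if val_f1 > best_f1:
            best_f1, best_epoch = val_f1, epoch
            best_params = {k: v.copy() for k, v in model.params.items()}
    model.params = best_params
    return TrainResult(
        model=model, pmi_table=table, log=log, best_epoch=best_epoch, parses=parses,
        train_instances=train_insts, val_instances=val_insts,
    )


# --------------------------------------------------------------------------
# evaluation

def evaluate(
    model: DDIMuGModel,
    test_instances,
    pmi_table: PmiTable,
    provider: ParserProvider | None = None,
    filter_policy: FilterPolicy | None = None,
    removed_policy: str = "score",
) -> EvalResult:
    """Filter, predict and score a test set.

    Instances removed by the preprocessing filters are, under the default
    ``removed_policy="score"``, scored as predicted Negative (they keep
    their gold labels, so filtered-out positives cost recall);
    ``"drop"`` excludes them from scoring entirely.
    """
    if removed_policy not in ("score", "drop"):
        raise ValueError(f"unknown removed_policy {removed_policy!r}")
    provider = provider or StubParserProvider()
    report = apply_filters(test_instances, filter_policy)
    parses = _parse_all(report.kept, provider, frozenset(model.config.verb_tag_set))
    preps = prepare_all(report.kept, parses, pmi_table, model)
    gold = [i.label for i in report.kept]
    pred = _predict_labels(model, preps)
    if removed_policy == "score":
        gold += [inst.label for inst, _rule in report.removed]
        pred += [NEGATIVE_LABEL] * len(report.removed)
    result = micro_prf(
        gold, pred,
        positive_labels=positive_labels(model.config.labels),
        labels=model.config.labels,
    )
    result.policy = removed_policy
    return result


# --------------------------------------------------------------------------
# explanation export

@dataclass
class Explanation:
    instance_id: str
    dep_edges: list  # (token_i, token_j, relation)
    cooc_edges: list  # (token_i, token_j, pmi_weight)
    verb_attention: list  # (verb surface, alpha)
    predicted_label: str
    probabilities: dict

    def to_dict(self) -> dict:
        return {
            "instance_id": self.instance_id,
            "dep_edges": [[i, j, r] for i, j, r in self.dep_edges],
            "cooc_edges": [[i, j, w] for i, j, w in self.cooc_edges],
            "verb_attention": [[v, a] for v, a in self.verb_attention],
            "predicted_label": self.predicted_label,
            "probabilities": self.probabilities,
        }


def explain(model: DDIMuGModel, prep: PreparedInstance) -> Explanation:
    """Export the edge and attention information behind one prediction.

    The dependency edge list and the positive-PMI co-occurrence edges come
    straight from the instance's graphs; verb attention is the softmax
    weight each verb received in the pooling layer.
    """
    probs, cache = model.forward(prep, want_cache=True)
    labels = model.config.labels
    parsed = prep.parsed
    dep_edges = [
        (e.head, e.dependent, e.relation)
        for e in parsed.edges
        if e.head >= 0
    ]
    cooc_edges = prep.word_adj_raw.edge_list()
    tokens = parsed.tokens
    verb_attention = [
        (tokens[v].surface, float(a))
        for v, a in zip(prep.verb_indices, cache["av"])
    ]
    return Explanation(
        instance_id=prep.instance_id,
        dep_edges=dep_edges,
        cooc_edges=cooc_edges,
        verb_attention=verb_attention,
        predicted_label=labels[int(np.argmax(probs))],
        probabilities={l: float(p) for l, p in zip(labels, probs)},
    )
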