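"""Synthetic DDI corpora with known ground truth.

Generates templated two-drug sentences whose relation label is determined
by a planted, class-predictive verb, mirroring the statistical structure
the model exploits in real corpora: a heavily Negative-skewed label
distribution, verb lexicons that predict the positive classes
(e.g. *inhibit/increase/decrease* for pharmacokinetic mechanisms,
*avoid/recommend/administer* for advice), and surface patterns (same
name, abbreviation, coordination) that the preprocessing filters must
catch. Sentences come with stub dependency parses, so no external parser
or network access is ever needed.

Also houses brute-force oracles (independent recounts, no shared code
with the production paths) used to validate the PMI machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

from ddimug.corpus_io import (
    DDI_LABELS,
    EntityMention,
    PairInstance,
    SentenceRecord,
    spans_to_charoffset,
)
from ddimug.linguistic import ParsedSentence, StubParserProvider, parse

DEFAULT_PRIORS = {
    "Negative": 0.70,
    "Advice": 0.075,
    "Effect": 0.075,
    "Mechanism": 0.075,
    "Int": 0.075,
}

#: Class-predictive verb lexicons; disjoint across labels. The Mechanism
#: and Advice sets follow the verb families most indicative of those
#: relations in the DDIExtraction corpus.
DEFAULT_VERB_LEXICON = {
    "Mechanism": ("inhibit", "increase", "decrease"),
    "Advice": ("avoid", "recommend", "administer"),
    "Effect": ("enhance", "potentiate", "prolong"),
    "Int": ("interact", "combine"),
}

DEFAULT_DRUG_POOL = (
    "aspirin", "warfarin", "heparin", "digoxin", "quinidine",
    "rifampin", "ketoconazole", "phenytoin", "cimetidine", "theophylline",
    "lithium", "ibuprofen", "metformin", "verapamil", "amiodarone",
    "fluoxetine", "erythromycin", "omeprazole", "simvastatin", "losartan",
)


@dataclass
class GeneratorConfig:
    n_sentences: int = 100
    class_priors: dict = field(default_factory=lambda: dict(DEFAULT_PRIORS))
    verb_lexicon: dict = field(default_factory=lambda: dict(DEFAULT_VERB_LEXICON))
    drug_pool: tuple = DEFAULT_DRUG_POOL
    # planted filterable sentences (all Negative), included in n_sentences
    plant_filter_patterns: dict = field(
        default_factory=lambda: {"same_name": 0, "abbreviation": 0, "coordination": 0}
    )
    seed: int = 0
    split: str = "train"

    def __post_init__(self):
        total = sum(self.class_priors.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class priors sum to {total}, expected 1")
        seen = set()
        for verbs in self.verb_lexicon.values():
            if seen & set(verbs):
                raise ValueError("verb lexicons must be disjoint across labels")
            seen |= set(verbs)
        if not self.drug_pool:
            raise ValueError("drug pool is empty")


@dataclass
class CorpusBundle:
    instances: list  # PairInstance
    parses: dict  # sentence_id -> ParsedSentence
    plan: dict  # ground truth: per-label counts, planted-pattern counts


def _positive_sentence(d1: str, verb: str, d2: str) -> tuple[str, int, int]:
    text = f"{d1} {verb}s the action of {d2} in patients ."
    return text, 0, text.index(d2, len(d1))


_NEGATIVE_TEMPLATES = (
    "{d1} was given before {d2} without any change .",
    "{d1} levels were measured while {d2} therapy continued .",
    "patients on {d1} also received {d2} during the study .",
)


def _make_instance(
    idx: int, text: str, d1: str, d2: str, p1: int, p2: int, label: str, split: str
) -> PairInstance:
    m1 = EntityMention("m1", ((p1, p1 + len(d1)),), d1)
    m2 = EntityMention("m2", ((p2, p2 + len(d2)),), d2)
    sent = SentenceRecord(f"s{idx}", text, (m1, m2))
    return PairInstance(
        instance_id=f"s{idx}.p0",
        sentence=sent,
        e1_id="m1",
        e2_id="m2",
        label=label,
        split=split,
        doc_id="synth",
    )


def generate_corpus(config: GeneratorConfig | None = None) -> CorpusBundle:
    """Deterministic synthetic corpus with its ground-truth plan.

    Per-label counts are drawn once from a seeded multinomial over the
    class priors; each positive sentence embeds a verb from its label's
    lexicon, so the verb identity fully determines the label. Planted
    filter-pattern sentences (same-name / abbreviation / coordination,
    all Negative) replace ordinary sentences, keeping the total at
    ``n_sentences``.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    plant = {k: int(v) for k, v in config.plant_filter_patterns.items()}
    n_planted = sum(plant.values())
    if n_planted > config.n_sentences:
        raise ValueError("more planted patterns than sentences")
    n_free = config.n_sentences - n_planted
    labels = sorted(config.class_priors)
    counts = rng.multinomial(n_free, [config.class_priors[l] for l in labels])
    label_seq = [l for l, c in zip(labels, counts) for _ in range(c)]
    rng.shuffle(label_seq)

    pool = list(config.drug_pool)
    instances: list[PairInstance] = []
    idx = 0

    def pick_two():
        i, j = rng.choice(len(pool), size=2, replace=False)
        return pool[i], pool[j]

    for rule, count in sorted(plant.items()):
        for _ in range(count):
            if rule == "same_name":
                d = pool[int(rng.integers(len(pool)))]
                text = f"{d} was given after {d} in the trial ."
                p1, p2 = 0, text.index(d, len(d))
                inst = _make_instance(idx, text, d, d, p1, p2, "Negative", config.split)
            elif rule == "abbreviation":
                d1, d2 = pick_two()
                if rng.random() < 0.5:
                    text = f"{d1} ({d2}) was studied in volunteers ."
                    p1, p2 = 0, text.index("(") + 1
                else:
                    text = f"{d1} such as {d2} can be considered ."
                    p1, p2 = 0, text.index(d2, len(d1))
                inst = _make_instance(idx, text, d1, d2, p1, p2, "Negative", config.split)
            elif rule == "coordination":
                d1, d2 = pick_two()
                rest = [d for d in pool if d not in (d1, d2)]
                dm = rest[int(rng.integers(len(rest)))]
                text = f"{d1} , {dm} , and {d2} were studied together ."
                p1 = 0
                pm = text.index(dm, len(d1))
                p2 = text.index(d2, pm + len(dm))
                m1 = EntityMention("m1", ((p1, p1 + len(d1)),), d1)
                mm = EntityMention("mm", ((pm, pm + len(dm)),), dm)
                m2 = EntityMention("m2", ((p2, p2 + len(d2)),), d2)
                sent = SentenceRecord(f"s{idx}", text, (m1, mm, m2))
                inst = PairInstance(
                    instance_id=f"s{idx}.p0",
                    sentence=sent,
                    e1_id="m1",
                    e2_id="m2",
                    label="Negative",
                    split=config.split,
                    doc_id="synth",
                )
            else:
                raise ValueError(f"unknown filter rule {rule!r}")
            instances.append(inst)
            idx += 1

    for label in label_seq:
        d1, d2 = pick_two()
        if label == "Negative":
            template = _NEGATIVE_TEMPLATES[int(rng.integers(len(_NEGATIVE_TEMPLATES)))]
            text = template.format(d1=d1, d2=d2)
            p1 = text.index(d1)
            p2 = text.index(d2, p1 + len(d1))
        else:
            verbs = config.verb_lexicon[label]
            verb = verbs[int(rng.integers(len(verbs)))]
            text, p1, p2 = _positive_sentence(d1, verb, d2)
        instances.append(_make_instance(idx, text, d1, d2, p1, p2, label, config.split))
        idx += 1

    provider = StubParserProvider()
    parses = {
        inst.sentence.sentence_id: parse(inst.sentence, provider)
        for inst in instances
    }
    plan = {
        "label_counts": {
            l: int(c) for l, c in zip(labels, counts)
        },
        "planted": plant,
        "n_sentences": config.n_sentences,
        "n_removed_expected": n_planted,
    }
    plan["label_counts"]["Negative"] = plan["label_counts"].get("Negative", 0) + n_planted
    return CorpusBundle(instances=instances, parses=parses, plan=plan)


# --------------------------------------------------------------------------
# brute-force oracles

def oracle_pmi(sentences, i: str, j: str) -> float:
    """Independent PMI recount by direct corpus scan (natural log).

    ``sentences`` are lemma iterables or parsed sentences; returns -inf
    when the pair never shares a window. Intentionally shares no code
    with the production PMI table.
    """
    sents = [
        s.lemmas() if isinstance(s, ParsedSentence) else list(s) for s in sentences
    ]
    total = len(sents)
    if i == j:
        joint = sum(1 for s in sents if s.count(i) >= 2)
    else:
        joint = sum(1 for s in sents if i in s and j in s)
    ci = sum(1 for s in sents if i in s)
    cj = sum(1 for s in sents if j in s)
    if joint == 0:
        return float("-inf")
    return math.log((joint / total) / ((ci / total) * (cj / total)))


# --------------------------------------------------------------------------
# fixture XML writer (tests only)

def make_fixture_semeval_xml(instances, path) -> Path:
    """Write instances as a SemEval-dialect XML file.

    charOffsets use the dialect's 0-based inclusive-end convention; pair
    elements carry ``ddi``/``type`` attributes derived from the label.
    """
    root = etree.Element("document", id="synthetic-fixture")
    by_sentence: dict[str, list[PairInstance]] = {}
    sentence_order = []
    for inst in instances:
        sid = inst.sentence.sentence_id
        if sid not in by_sentence:
            by_sentence[sid] = []
            sentence_order.append(sid)
        by_sentence[sid].append(inst)
    for sid in sentence_order:
        insts = by_sentence[sid]
        sent = insts[0].sentence
        sent_el = etree.SubElement(root, "sentence", id=sid, text=sent.text)
        for m in sent.mentions:
            etree.SubElement(
                sent_el,
                "entity",
                id=f"{sid}.{m.mention_id}",
                charOffset=spans_to_charoffset(m.spans),
                type=m.entity_type,
                text=m.text,
            )
        for k, inst in enumerate(insts):
            attrs = {
                "id": f"{sid}.pair{k}",
                "e1": f"{sid}.{inst.e1_id}",
                "e2": f"{sid}.{inst.e2_id}",
            }
            if inst.label == "Negative":
                attrs["ddi"] = "false"
            else:
                attrs["ddi"] = "true"
                attrs["type"] = "advise" if inst.label == "Advice" else inst.label.lower()
            etree.SubElement(sent_el, "pair", **attrs)
    path = Path(path)
    path.write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    )
    return path
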