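"""Corpus readers/writers and label statistics for DDI relation extraction.

Supports the SemEval-2013 Task 9 (DDIExtraction) XML dialect and a generic
JSONL instance format. Each instance is one candidate drug pair in one
sentence with a gold relation label. The DDIExtraction label set is
``{Advice, Effect, Mechanism, Int, Negative}``; the TAC 2018 sentence-level
set is ``{Pharmacokinetic, Pharmacodynamic, Unspecified, Negative}``.
``Negative`` is the only negative-polarity label in either set.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

DDI_LABELS = ("Advice", "Effect", "Mechanism", "Int", "Negative")
TAC_LABELS = ("Pharmacokinetic", "Pharmacodynamic", "Unspecified", "Negative")
NEGATIVE_LABEL = "Negative"

# SemEval "type" attribute values -> canonical labels
_SEMEVAL_TYPE_MAP = {
    "advise": "Advice",
    "advice": "Advice",
    "effect": "Effect",
    "mechanism": "Mechanism",
    "int": "Int",
}


class CorpusError(ValueError):
    """Malformed corpus file or inconsistent annotation."""


def positive_labels(label_set=DDI_LABELS) -> tuple[str, ...]:
    """All labels of positive polarity (everything except Negative)."""
    return tuple(l for l in label_set if l != NEGATIVE_LABEL)


@dataclass(frozen=True)
class EntityMention:
    """A gold drug-name span, possibly discontinuous.

    Spans are stored 0-based half-open; the SemEval charOffset dialect
    (0-based inclusive-end) is converted on read by
    :func:`charoffset_to_spans`, the single point of dialect truth.
    """

    mention_id: str
    spans: tuple[tuple[int, int], ...]
    text: str
    entity_type: str = "drug"

    def __post_init__(self):
        if not self.spans:
            raise CorpusError(f"mention {self.mention_id}: empty span list")
        for s, e in self.spans:
            if s >= e:
                raise CorpusError(
                    f"mention {self.mention_id}: degenerate span ({s},{e})"
                )
        flat = list(self.spans)
        if flat != sorted(flat):
            raise CorpusError(f"mention {self.mention_id}: spans not sorted")
        for (_, e1), (s2, _) in zip(flat, flat[1:]):
            if s2 < e1:
                raise CorpusError(f"mention {self.mention_id}: overlapping spans")

    @property
    def first_span(self) -> tuple[int, int]:
        return self.spans[0]


@dataclass(frozen=True)
class SentenceRecord:
    sentence_id: str
    text: str
    mentions: tuple[EntityMention, ...] = ()

    def __post_init__(self):
        ids = [m.mention_id for m in self.mentions]
        if len(ids) != len(set(ids)):
            raise CorpusError(f"sentence {self.sentence_id}: duplicate mention ids")
        for m in self.mentions:
            got = " ".join(self.text[s:e] for s, e in m.spans)
            want = " ".join(m.text.split())
            if " ".join(got.split()) != want:
                raise CorpusError(
                    f"sentence {self.sentence_id}: mention {m.mention_id} text "
                    f"{m.text!r} does not match span substring {got!r}"
                )

    def mention(self, mention_id: str) -> EntityMention:
        for m in self.mentions:
            if m.mention_id == mention_id:
                return m
        raise CorpusError(
            f"sentence {self.sentence_id}: unknown mention id {mention_id!r}"
        )


@dataclass(frozen=True)
class PairInstance:
    """One candidate drug pair in one sentence with its gold label."""

    instance_id: str
    sentence: SentenceRecord
    e1_id: str
    e2_id: str
    label: str
    split: str = "other"
    doc_id: str = ""

    def __post_init__(self):
        if self.e1_id == self.e2_id:
            raise CorpusError(f"instance {self.instance_id}: e1 == e2")
        self.sentence.mention(self.e1_id)
        self.sentence.mention(self.e2_id)

    @property
    def e1(self) -> EntityMention:
        return self.sentence.mention(self.e1_id)

    @property
    def e2(self) -> EntityMention:
        return self.sentence.mention(self.e2_id)


def charoffset_to_spans(charoffset: str) -> tuple[tuple[int, int], ...]:
    """Parse a SemEval charOffset string into half-open spans.

    The dialect is ``"start-end"`` with 0-based *inclusive* end, and
    ``";"`` separating the pieces of a discontinuous mention:
    ``"12-18;25-30"`` -> ``((12, 19), (25, 31))``.
    """
    spans = []
    for piece in charoffset.split(";"):
        start_s, _, end_s = piece.partition("-")
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise CorpusError(f"bad charOffset piece {piece!r}") from exc
        spans.append((start, end + 1))
    return tuple(spans)


def spans_to_charoffset(spans) -> str:
    """Inverse of :func:`charoffset_to_spans`."""
    return ";".join(f"{s}-{e - 1}" for s, e in spans)


def read_semeval_xml(path, split: str = "other") -> list[PairInstance]:
    """Read SemEval-2013 Task 9 XML file(s) into pair instances.

    ``path`` may be a single ``.xml`` file or a directory that is walked
    recursively. Each ``<pair>`` element yields one instance:
    ``ddi="false"`` maps to Negative, ``ddi="true"`` maps its ``type``
    attribute to the positive label.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    files = sorted(path.rglob("*.xml")) if path.is_dir() else [path]
    instances: list[PairInstance] = []
    for f in files:
        instances.extend(_read_one_xml(f, split))
    return instances


def _read_one_xml(path: Path, split: str) -> list[PairInstance]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    doc_id = root.get("id", path.stem)
    out: list[PairInstance] = []
    for sent_el in root.iter("sentence"):
        text = sent_el.get("text", "")
        mentions = []
        for ent in sent_el.iter("entity"):
            spans = charoffset_to_spans(ent.get("charOffset"))
            mentions.append(
                EntityMention(
                    mention_id=ent.get("id"),
                    spans=spans,
                    text=ent.get("text"),
                    entity_type=ent.get("type", "drug"),
                )
            )
        sentence = SentenceRecord(
            sentence_id=sent_el.get("id"), text=text, mentions=tuple(mentions)
        )
        known = {m.mention_id for m in mentions}
        for pair in sent_el.iter("pair"):
            pid = pair.get("id")
            e1, e2 = pair.get("e1"), pair.get("e2")
            for eid in (e1, e2):
                if eid not in known:
                    raise CorpusError(
                        f"{path}: pair {pid} references unknown entity {eid!r}"
                    )
            ddi = (pair.get("ddi") or "").lower()
            if ddi == "false":
                label = NEGATIVE_LABEL
            elif ddi == "true":
                type_attr = pair.get("type")
                if type_attr is None:
                    raise CorpusError(
                        f"{path}: pair {pid} has ddi='true' but no type attribute"
                    )
                try:
                    label = _SEMEVAL_TYPE_MAP[type_attr.lower()]
                except KeyError as exc:
                    raise CorpusError(
                        f"{path}: pair {pid} has unknown type {type_attr!r}"
                    ) from exc
            else:
                raise CorpusError(f"{path}: pair {pid} has ddi={ddi!r}")
            out.append(
                PairInstance(
                    instance_id=pid,
                    sentence=sentence,
                    e1_id=e1,
                    e2_id=e2,
                    label=label,
                    split=split,
                    doc_id=doc_id,
                )
            )
    return out


# --- generic JSONL format -------------------------------------------------
# One instance per line:
# {"instance_id", "doc_id", "split", "sentence_id", "text",
#  "mentions": [{"id", "spans": [[s,e],...], "text", "type"}],
#  "e1", "e2", "label"}

_REQUIRED_KEYS = (
    "instance_id",
    "doc_id",
    "split",
    "sentence_id",
    "text",
    "mentions",
    "e1",
    "e2",
    "label",
)


def instance_to_dict(inst: PairInstance) -> dict:
    return {
        "instance_id": inst.instance_id,
        "doc_id": inst.doc_id,
        "split": inst.split,
        "sentence_id": inst.sentence.sentence_id,
        "text": inst.sentence.text,
        "mentions": [
            {
                "id": m.mention_id,
                "spans": [list(s) for s in m.spans],
                "text": m.text,
                "type": m.entity_type,
            }
            for m in inst.sentence.mentions
        ],
        "e1": inst.e1_id,
        "e2": inst.e2_id,
        "label": inst.label,
    }


def instance_from_dict(d: dict, lineno: int | None = None) -> PairInstance:
    where = f" at line {lineno}" if lineno is not None else ""
    for key in _REQUIRED_KEYS:
        if key not in d:
            raise CorpusError(f"missing required key {key!r}{where}")
    mentions = tuple(
        EntityMention(
            mention_id=m["id"],
            spans=tuple((int(s), int(e)) for s, e in m["spans"]),
            text=m["text"],
            entity_type=m.get("type", "drug"),
        )
        for m in d["mentions"]
    )
    sentence = SentenceRecord(
        sentence_id=d["sentence_id"], text=d["text"], mentions=mentions
    )
    return PairInstance(
        instance_id=d["instance_id"],
        sentence=sentence,
        e1_id=d["e1"],
        e2_id=d["e2"],
        label=d["label"],
        split=d["split"],
        doc_id=d["doc_id"],
    )


def read_jsonl(path) -> list[PairInstance]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"bad JSON at line {lineno}: {exc}") from exc
            out.append(instance_from_dict(d, lineno))
    return out


def write_jsonl(instances, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            fh.write(json.dumps(instance_to_dict(inst), ensure_ascii=False))
            fh.write("\n")


@dataclass
class CorpusStats:
    per_split: dict = field(default_factory=dict)  # split -> Counter(label)
    overall: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.overall.values())


def corpus_stats(instances) -> CorpusStats:
    """Per-label instance counts, per split and overall."""
    stats = CorpusStats()
    for inst in instances:
        stats.per_split.setdefault(inst.split, Counter())[inst.label] += 1
        stats.overall[inst.label] += 1
    return stats
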