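"""Negative-instance filtering for DDI candidate pairs.

Candidate pairs that trivially cannot interact are removed before training
and evaluation by three surface rules: (1) both drugs have the same name —
a drug does not interact with itself; (2) one drug is an abbreviation or a
particular case of the other ("DRUG-A (DRUG-B)", "DRUG-A such as DRUG-B");
(3) both drugs sit in one coordinate list ("DRUG-A, DRUG-N, ..., DRUG-B").
Rules fire on the surface text only; parse-based coordination detection is
deliberately out of scope.

Rule precedence is fixed (same_name, abbreviation, coordination) so the
per-rule attribution is deterministic; which instances are removed in
total does not depend on the order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from ddimug.corpus_io import PairInstance

DEFAULT_ABBREV_CUES = ("(", "such as", "e.g.", "i.e.", "known as", "called")
RULE_NAMES = ("same_name", "abbreviation", "coordination")

_COORD_CONJ = re.compile(r"\b(?:and|or)\b", re.IGNORECASE)


def _normalize_name(text: str) -> str:
    return " ".join(text.casefold().split())


def rule_same_name(instance: PairInstance) -> bool:
    """True iff the two drug names are equal after case/whitespace folding."""
    return _normalize_name(instance.e1.text) == _normalize_name(instance.e2.text)


def _inter_entity_text(instance: PairInstance) -> str:
    """Sentence text strictly between the two mention spans ('' if overlapping)."""
    a, b = instance.e1.first_span, instance.e2.first_span
    if a[0] > b[0]:
        a, b = b, a
    if a[1] >= b[0]:
        return ""
    return instance.sentence.text[a[1] : b[0]]


def rule_abbreviation(instance: PairInstance, cues=DEFAULT_ABBREV_CUES) -> bool:
    """True iff the second drug looks like an abbreviation/special case of
    the first: the inter-entity text is exactly an apposition cue, or an
    opening parenthesis that the second mention closes."""
    between = _inter_entity_text(instance).strip()
    if not between:
        return False
    for cue in cues:
        if cue == "(":
            # "A (B)" -- paren opens right after e1 and closes right after e2
            if between == "(":
                text = instance.sentence.text
                later = max(instance.e1.first_span, instance.e2.first_span)
                tail = text[later[1] :].lstrip()
                if tail.startswith(")"):
                    return True
        elif between.strip(" ,").casefold() == cue.casefold():
            return True
    return False


def rule_coordination(instance: PairInstance) -> bool:
    """True iff both drugs are members of one comma/and/or coordinate list.

    Every maximal text segment between the two mentions must consist only
    of other tagged drug mentions separated by commas and/or the
    conjunctions ``and``/``or`` (whitespace allowed). Any other token —
    including ";" — breaks the list.
    """
    sent = instance.sentence
    a, b = instance.e1.first_span, instance.e2.first_span
    if a[0] > b[0]:
        a, b = b, a
    if a[1] >= b[0]:
        return False
    lo, hi = a[1], b[0]
    # mask out the other drug mentions lying wholly between the pair
    segment = sent.text[lo:hi]
    holes = []
    for m in sent.mentions:
        if m.mention_id in (instance.e1_id, instance.e2_id):
            continue
        for s, e in m.spans:
            if s >= lo and e <= hi:
                holes.append((s - lo, e - lo))
    masked = list(segment)
    for s, e in holes:
        for i in range(s, e):
            masked[i] = " "
    residue = "".join(masked)
    residue = _COORD_CONJ.sub(" ", residue)
    residue = residue.replace(",", " ")
    return residue.strip() == ""


_RULES = {
    "same_name": lambda inst, cues: rule_same_name(inst),
    "abbreviation": lambda inst, cues: rule_abbreviation(inst, cues),
    "coordination": lambda inst, cues: rule_coordination(inst),
}


@dataclass
class FilterPolicy:
    enabled: bool = True
    abbrev_cues: tuple = DEFAULT_ABBREV_CUES
    # None -> rules apply to all labels (matching reported corpus statistics
    # where a few positive instances are removed as well)
    apply_to_labels: tuple | None = None


@dataclass
class FilterReport:
    kept: list = field(default_factory=list)
    removed: list = field(default_factory=list)  # (instance, rule_name)
    per_rule_counts: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def apply_filters(instances, policy: FilterPolicy | None = None) -> FilterReport:
    """Partition instances into kept/removed by the three rules.

    The first rule that fires (in fixed precedence order) is recorded for
    each removed instance.
    """
    policy = policy or FilterPolicy()
    report = FilterReport(per_rule_counts={r: 0 for r in RULE_NAMES})
    if not policy.enabled:
        report.kept = list(instances)
        return report
    for inst in instances:
        fired = None
        if policy.apply_to_labels is None or inst.label in policy.apply_to_labels:
            for rule in RULE_NAMES:
                if _RULES[rule](inst, policy.abbrev_cues):
                    fired = rule
                    break
        if fired is None:
            report.kept.append(inst)
        else:
            report.removed.append((inst, fired))
            report.per_rule_counts[fired] += 1
    return report
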