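"""Tokenization, POS tagging, lemmatization and dependency parsing.

Real parsers (Stanford/UD-style) plug in behind :class:`ParserProvider`;
the package ships a deterministic :class:`StubParserProvider` so every
downstream stage is testable offline. The stub produces a left-headed
chain (token *i* headed by *i*-1), lowercased-surface lemmas, and POS tags
from a small lexicon — structurally a valid dependency tree, which is all
the graph machinery requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ddimug.corpus_io import SentenceRecord

ROOT = -1  # head sentinel for the tree root

#: Penn-Treebank verb family; the default definition of "verb" for the
#: verb-aspect stream. Configurable because taggers differ.
DEFAULT_VERB_TAGS = frozenset({"VB", "VBD", "VBG", "VBN", "VBP", "VBZ"})


class ParseError(RuntimeError):
    pass


@dataclass(frozen=True)
class Token:
    index: int
    surface: str
    lemma: str
    pos: str
    char_span: tuple[int, int]  # half-open


@dataclass(frozen=True)
class DepEdge:
    head: int  # token index, or ROOT
    dependent: int
    relation: str


@dataclass
class ParsedSentence:
    sentence_id: str
    tokens: list[Token]
    edges: list[DepEdge]
    mention_token_spans: dict = field(default_factory=dict)  # id -> (lo, hi) half-open
    verb_indices: list[int] = field(default_factory=list)

    def lemmas(self) -> list[str]:
        return [t.lemma for t in self.tokens]

    def validate_tree(self) -> None:
        """Assert the dependency edges form a tree over the tokens."""
        n = len(self.tokens)
        if len(self.edges) != n:
            raise ParseError(
                f"{self.sentence_id}: {len(self.edges)} edges for {n} tokens"
            )
        heads = {}
        roots = 0
        for e in self.edges:
            if e.dependent in heads:
                raise ParseError(f"{self.sentence_id}: token {e.dependent} has two heads")
            if e.head == e.dependent:
                raise ParseError(f"{self.sentence_id}: self-loop at {e.dependent}")
            heads[e.dependent] = e.head
            if e.head == ROOT:
                roots += 1
        if roots != 1:
            raise ParseError(f"{self.sentence_id}: {roots} roots (expected 1)")
        # acyclicity: walking up from any token must reach ROOT
        for tok in range(n):
            seen = set()
            cur = tok
            while cur != ROOT:
                if cur in seen:
                    raise ParseError(f"{self.sentence_id}: cycle through {cur}")
                seen.add(cur)
                cur = heads.get(cur, ROOT)


class ParserProvider:
    """Contract: deterministic text -> (tokens, tree, POS, lemma)."""

    name = "abstract"

    def parse_text(self, text: str) -> tuple[list[Token], list[DepEdge]]:
        raise NotImplementedError


# Minimal POS lexicon for the stub provider. Covers the verb families the
# synthetic generator plants, plus a handful of function words; everything
# else is tagged NN.
_STUB_POS = {
    "and": "CC", "or": "CC", "but": "CC",
    "the": "DT", "a": "DT", "an": "DT",
    "of": "IN", "with": "IN", "in": "IN", "to": "TO",
    "may": "MD", "should": "MD", "can": "MD",
    "is": "VBZ", "are": "VBP", "was": "VBD", "be": "VB",
}
_STUB_VERB_STEMS = (
    "inhibit", "increase", "decrease", "avoid", "recommend", "administer",
    "enhance", "reduce", "potentiate", "antagonize", "alter", "affect",
    "coadminister", "combine", "interact", "prolong",
)


def _stub_pos(surface: str) -> str:
    low = surface.lower()
    if low in _STUB_POS:
        return _STUB_POS[low]
    for stem in _STUB_VERB_STEMS:
        if low.startswith(stem):
            if low.endswith("ed"):
                return "VBD"
            if low.endswith("ing"):
                return "VBG"
            if low.endswith("s"):
                return "VBZ"
            return "VB"
    return "NN"


def _stub_lemma(surface: str) -> str:
    low = surface.lower()
    for stem in _STUB_VERB_STEMS:
        if low.startswith(stem):
            return stem
    return low


class StubParserProvider(ParserProvider):
    """Deterministic offline parser: whitespace/punct tokens, left-headed
    chain with relation ``"stub"``, lexicon POS, lowercase-stem lemmas."""

    name = "stub"

    def parse_text(self, text: str) -> tuple[list[Token], list[DepEdge]]:
        tokens: list[Token] = []
        i = 0
        n = len(text)
        while i < n:
            if text[i].isspace():
                i += 1
                continue
            if text[i].isalnum() or text[i] in "-'":
                j = i
                while j < n and (text[j].isalnum() or text[j] in "-'"):
                    j += 1
            else:
                j = i + 1  # punctuation: one char per token
            surface = text[i:j]
            tokens.append(
                Token(
                    index=len(tokens),
                    surface=surface,
                    lemma=_stub_lemma(surface),
                    pos=_stub_pos(surface),
                    char_span=(i, j),
                )
            )
            i = j
        edges = [
            DepEdge(head=k - 1 if k > 0 else ROOT, dependent=k, relation="stub")
            for k in range(len(tokens))
        ]
        return tokens, edges


PROVIDERS: dict[str, type[ParserProvider]] = {"stub": StubParserProvider}


def get_provider(name: str) -> ParserProvider:
    try:
        return PROVIDERS[name]()
    except KeyError as exc:
        raise KeyError(
            f"unknown parser provider {name!r}; registered: {sorted(PROVIDERS)}"
        ) from exc


def parse(
    sentence: SentenceRecord,
    provider: ParserProvider,
    verb_tags=DEFAULT_VERB_TAGS,
) -> ParsedSentence:
    """Parse a sentence and resolve mentions to token ranges.

    A mention maps to the contiguous run of tokens its first character
    span overlaps (discontinuous mentions use the first span, which
    carries the head drug name).
    """
    try:
        tokens, edges = provider.parse_text(sentence.text)
    except Exception as exc:  # provider failure carries the sentence id
        raise ParseError(f"parse failed for {sentence.sentence_id}: {exc}") from exc
    parsed = ParsedSentence(sentence_id=sentence.sentence_id, tokens=tokens, edges=edges)
    parsed.validate_tree()
    for m in sentence.mentions:
        s, e = m.first_span
        idxs = [t.index for t in tokens if t.char_span[0] < e and t.char_span[1] > s]
        if not idxs:
            raise ParseError(
                f"{sentence.sentence_id}: mention {m.mention_id} overlaps no token"
            )
        parsed.mention_token_spans[m.mention_id] = (idxs[0], idxs[-1] + 1)
    parsed.verb_indices = identify_verbs(parsed, verb_tags)
    return parsed


def identify_verbs(parsed: ParsedSentence, verb_tags=DEFAULT_VERB_TAGS) -> list[int]:
    """Indices of tokens whose POS tag is in the verb-tag set."""
    return [t.index for t in parsed.tokens if t.pos in verb_tags]


def lemmatize_tokens(tokens, provider: ParserProvider | None = None) -> list[Token]:
    """Ensure every token carries a lowercased, non-empty lemma."""
    out = []
    for t in tokens:
        lemma = (t.lemma or t.surface).lower()
        out.append(Token(t.index, t.surface, lemma, t.pos, t.char_span))
    return out
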