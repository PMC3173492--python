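"""Extract candidate phrases (nouns, adjectives, noun phrases) with in-document counts.

The extraction pipeline mirrors standard keyphrase practice: split text into
sentences, tokenize into words, tag parts of speech, then chunk out single
nouns (N), single adjectives (A), and multi-word noun phrases — contiguous
runs of adjectives/nouns ending in a noun (patterns AN, NN, ANN, ...).
Every contiguous noun-terminated sub-span of a run is emitted, so a run
like ``xenopus/N laevis/N cement/N gland/N`` yields "cement gland",
"laevis cement gland", "xenopus laevis cement gland", etc.

Counting is per emission: a phrase's ``doc_count`` is the number of times
its (case-folded) token sequence is emitted across all sentences of the
document, which makes doc_count monotone under sub-spans — a sub-span is
emitted at least as often as any span containing it.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from litnav.corpus_model import BackgroundCounts, DocumentRecord
from litnav.tagging import Tagger, coarse_tag, default_tagger

__all__ = [
    "TaggedToken",
    "CandidatePhrase",
    "PhraseStats",
    "split_sentences",
    "tokenize_words",
    "tag_tokens",
    "chunk_phrases",
    "count_phrases",
    "attach_background",
]

DEFAULT_MAX_PHRASE_LEN = 5  # longest useful query phrases run ~4 tokens

COARSE_TAGS = frozenset({"NOUN", "ADJ", "OTHER"})


@dataclass(frozen=True)
class TaggedToken:
    token: str
    tag: str  # NOUN | ADJ | OTHER

    def __post_init__(self) -> None:
        if not self.token:
            raise ValueError("empty token")
        if self.tag not in COARSE_TAGS:
            raise ValueError(f"tag must be one of {sorted(COARSE_TAGS)}, got {self.tag!r}")


@dataclass(frozen=True)
class CandidatePhrase:
    """A candidate search phrase: canonical case-folded tokens plus tag pattern.

    Identity (equality/hash) is the token sequence alone; ``pattern`` (e.g.
    "AN") and ``surface`` (the first-seen original-cased form, kept for
    display and quoted search) are metadata.
    """

    tokens: tuple[str, ...]
    pattern: str = field(compare=False, default="")
    surface: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if not self.tokens or any(not t for t in self.tokens):
            raise ValueError("phrase tokens must be non-empty")

    @property
    def text(self) -> str:
        return " ".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class PhraseStats:
    """A candidate phrase with its document count and background count."""

    phrase: CandidatePhrase
    doc_count: int
    bg_count: int | None = None  # unset until attach_background

    def __post_init__(self) -> None:
        if self.doc_count < 1:
            raise ValueError("doc_count must be >= 1: a counted phrase occurred")
        if self.bg_count is not None and self.bg_count < 0:
            raise ValueError("bg_count must be >= 0")


_ABBREVIATIONS = frozenset(
    "dr mr mrs ms prof st no vs etc fig figs eq ref refs al cf ca approx inc ltd jr sr vol pp ed eds".split()
)
_BOUNDARY_RE = re.compile(r"[.!?]+(?=(\s+))")
_NEXT_START_RE = re.compile(r'["\'(\[]?[A-Z0-9]')


def split_sentences(text: str) -> list[str]:
    """Split text into sentences at ``. ! ?`` boundaries.

    A period is a boundary only when followed by whitespace and an
    upper-case/digit sentence opener, and the preceding word is neither a
    known abbreviation nor a single initial — so "Dr. Smith ran." is one
    sentence. Concatenating the output (modulo boundary whitespace)
    reproduces the input.
    """
    sentences: list[str] = []
    start = 0
    for match in _BOUNDARY_RE.finditer(text):
        end = match.end()
        preceding = text[start:match.start()]
        last_word = preceding.split()[-1] if preceding.split() else ""
        last_word = last_word.rstrip(".").casefold()
        follow = text[end:].lstrip()
        if not _NEXT_START_RE.match(follow):
            continue
        if last_word in _ABBREVIATIONS or (len(last_word) == 1 and last_word.isalpha()):
            continue
        sentence = text[start:end].strip()
        if sentence:
            sentences.append(sentence)
        start = end
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


_TOKEN_RE = re.compile(
    r"[A-Za-z0-9](?:[A-Za-z0-9'\-/+]*[A-Za-z0-9])?"  # words; hyphenated tokens stay intact
    r"|[^\sA-Za-z0-9]"  # each punctuation mark is its own token
)


def tokenize_words(sentence: str) -> list[str]:
    return _TOKEN_RE.findall(sentence)


def tag_tokens(sentence: str, tagger: Tagger | None = None) -> list[TaggedToken]:
    """Tokenize a sentence and tag each token with a coarse {NOUN, ADJ, OTHER} tag.

    The tagger contract maps a token list to equal-length fine Penn-style
    tags, which are reduced through the shipped tag map. Tagging errors are
    expected (taggers run ~90-97% accuracy) and flow through uncorrected.
    """
    tokens = tokenize_words(sentence)
    if not tokens:
        return []
    tagger = tagger or default_tagger()
    fine_tags = tagger(tokens)
    if len(fine_tags) != len(tokens):
        raise ValueError(
            f"tagger returned {len(fine_tags)} tags for {len(tokens)} tokens"
        )
    return [TaggedToken(tok, coarse_tag(tag)) for tok, tag in zip(tokens, fine_tags)]


def chunk_phrases(
    tagged: Sequence[TaggedToken], max_phrase_len: int = DEFAULT_MAX_PHRASE_LEN
) -> list[CandidatePhrase]:
    """Emit candidate phrases from one tagged sentence (with repetition).

    Emits every single NOUN token, every single ADJ token, and — within each
    maximal run of ADJ/NOUN tokens — every contiguous sub-span of length
    2..max_phrase_len whose last token is a NOUN.  Tokens are case-folded
    for identity; the original-cased surface form is retained.
    """
    if max_phrase_len < 1:
        raise ValueError("max_phrase_len must be >= 1")
    out: list[CandidatePhrase] = []

    def emit(span: Sequence[TaggedToken]) -> None:
        out.append(
            CandidatePhrase(
                tokens=tuple(t.token.casefold() for t in span),
                pattern="".join("N" if t.tag == "NOUN" else "A" for t in span),
                surface=" ".join(t.token for t in span),
            )
        )

    for tok in tagged:
        if tok.tag in ("NOUN", "ADJ"):
            emit([tok])

    i = 0
    n = len(tagged)
    while i < n:
        if tagged[i].tag not in ("NOUN", "ADJ"):
            i += 1
            continue
        j = i
        while j < n and tagged[j].tag in ("NOUN", "ADJ"):
            j += 1
        run = tagged[i:j]
        for a in range(len(run)):
            for b in range(a + 2, min(a + max_phrase_len, len(run)) + 1):
                if run[b - 1].tag == "NOUN":
                    emit(run[a:b])
        i = j
    return out


def count_phrases(
    doc: DocumentRecord,
    tagger: Tagger | None = None,
    max_phrase_len: int = DEFAULT_MAX_PHRASE_LEN,
) -> list[PhraseStats]:
    """Extract and count distinct candidate phrases over a document's text.

    Text = title + abstract + body prose (reference lists are excluded at
    read time).  A sentence on which the tagger raises is skipped with a
    warning so one bad sentence cannot sink the document.
    """
    if not doc.text_blocks:
        raise ValueError(f"document {doc.doc_id} has no text")
    counts: dict[CandidatePhrase, int] = {}
    first_seen: dict[CandidatePhrase, CandidatePhrase] = {}
    for block in doc.text_blocks:
        for sentence in split_sentences(block):
            try:
                tagged = tag_tokens(sentence, tagger)
            except Exception as exc:  # fault isolation per sentence
                warnings.warn(
                    f"tagger failed on sentence in {doc.doc_id!r}: {exc}", stacklevel=2
                )
                continue
            for phrase in chunk_phrases(tagged, max_phrase_len):
                counts[phrase] = counts.get(phrase, 0) + 1
                first_seen.setdefault(phrase, phrase)
    return [
        PhraseStats(phrase=first_seen[p], doc_count=c) for p, c in counts.items()
    ]


def attach_background(
    stats: Iterable[PhraseStats], provider: BackgroundCounts
) -> list[PhraseStats]:
    """Fill in each phrase's background count from a total provider (absent -> 0)."""
    out = []
    for s in stats:
        s.bg_count = int(provider(s.phrase.text))
        out.append(s)
    return out
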