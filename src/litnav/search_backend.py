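"""Quoted exact-phrase search over a corpus: local inverted index plus remote adapter.

The local backend mimics the behaviour of a recency-ordered abstract/title
search service: a query phrase matches a document when the exact token
sequence occurs contiguously within the title or within the abstract
(case-insensitive, never across the field boundary), and results are
returned newest-first, truncated to the top N (20 by default — the slice
of a result list users actually inspect).
"""

from __future__ import annotations

import datetime as _dt
import json
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from litnav.corpus_model import BackgroundCounts, Corpus, DocumentRecord
from litnav.phrase_extraction import tokenize_words

__all__ = [
    "SearchOutcome",
    "PhraseIndex",
    "build_index",
    "phrase_search",
    "background_count_provider",
    "RemoteSearchError",
    "RemoteConfig",
    "remote_search",
    "DEFAULT_TOP_N",
]

DEFAULT_TOP_N = 20

_EPOCH = _dt.date.min


@dataclass(frozen=True)
class SearchOutcome:
    """One quoted-phrase query and its truncated, ordered result list."""

    term: str
    result_ids: tuple[str, ...]
    total_hits: int
    truncated_at: int

    def __post_init__(self) -> None:
        if len(self.result_ids) > self.truncated_at:
            raise ValueError("more results than the truncation limit")
        if len(set(self.result_ids)) != len(self.result_ids):
            raise ValueError("duplicate result ids")
        if self.total_hits < len(self.result_ids):
            raise ValueError("total_hits below the returned result count")


def _canon_tokens(text: str) -> tuple[str, ...]:
    # word tokens only: quoted phrase matching ignores punctuation
    return tuple(t.casefold() for t in tokenize_words(text) if any(ch.isalnum() for ch in t))


def _contains_contiguous(haystack: tuple[str, ...], needle: tuple[str, ...]) -> bool:
    n = len(needle)
    if n == 0 or n > len(haystack):
        return False
    first = needle[0]
    for i in range(len(haystack) - n + 1):
        if haystack[i] == first and haystack[i : i + n] == needle:
            return True
    return False


class PhraseIndex:
    """Inverted token index over title + abstract, supporting exact phrase lookup."""

    def __init__(self, corpus: Corpus) -> None:
        if len(corpus) == 0:
            raise ValueError("cannot index an empty corpus")
        self.corpus = corpus
        self._fields: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {}
        self._postings: dict[str, set[str]] = {}
        for rec in corpus:
            title = _canon_tokens(rec.title)
            abstract = _canon_tokens(rec.abstract)
            self._fields[rec.doc_id] = (title, abstract)
            for tok in set(title) | set(abstract):
                self._postings.setdefault(tok, set()).add(rec.doc_id)

    def __len__(self) -> int:
        return len(self._fields)

    def candidates(self, tokens: Sequence[str]) -> set[str]:
        sets = [self._postings.get(t, set()) for t in tokens]
        if not sets or any(not s for s in sets):
            return set()
        return set.intersection(*sets)

    def matches(self, doc_id: str, tokens: tuple[str, ...]) -> bool:
        title, abstract = self._fields[doc_id]
        return _contains_contiguous(title, tokens) or _contains_contiguous(abstract, tokens)


def build_index(corpus: Corpus) -> PhraseIndex:
    return PhraseIndex(corpus)


def _recency_key(rec: DocumentRecord) -> tuple:
    # newest first, ties broken by doc_id descending — deterministic
    date = rec.pub_date or _EPOCH
    return (date, rec.doc_id)


def phrase_search(index: PhraseIndex, term: str, top_n: int = DEFAULT_TOP_N) -> SearchOutcome:
    """Run a quoted phrase query: contiguous token-sequence match in title or abstract.

    Results are ordered by publication date descending (doc_id descending on
    ties) and truncated to ``top_n``; ``total_hits`` is the untruncated
    match count.
    """
    tokens = _canon_tokens(term)
    if not tokens:
        raise ValueError(f"term {term!r} is empty after tokenization")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    hits = [
        index.corpus[doc_id]
        for doc_id in index.candidates(tokens)
        if index.matches(doc_id, tokens)
    ]
    hits.sort(key=_recency_key, reverse=True)
    return SearchOutcome(
        term=term,
        result_ids=tuple(rec.doc_id for rec in hits[:top_n]),
        total_hits=len(hits),
        truncated_at=top_n,
    )


def background_count_provider(table: BackgroundCounts) -> Callable[[str], int]:
    """Wrap a count table as the provider contract: a total callable phrase -> count."""
    return table


class RemoteSearchError(RuntimeError):
    """Typed failure from the remote search adapter after bounded retries."""


@dataclass
class RemoteConfig:
    """Configuration for an esearch-style remote endpoint.

    ``field_tag`` restricts matching to titles/abstracts; set to "" for
    global search.  Responses are cached to ``cache_path`` keyed by
    (term, date) so recorded sessions replay without network.
    """

    base_url: str = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"
    api_key: str | None = None
    rate_limit_per_s: float = 3.0
    max_retries: int = 3
    field_tag: str = "[Title/Abstract]"
    cache_path: str | None = None


def remote_search(term: str, top_n: int = DEFAULT_TOP_N, config: RemoteConfig | None = None) -> SearchOutcome:
    """Quoted phrase search against a remote E-utilities-style endpoint.

    Same contract as :func:`phrase_search`.  Network use is opt-in; all
    benchmark paths run against the local index or a recorded cache.
    """
    config = config or RemoteConfig()
    if not term.strip():
        raise ValueError("empty search term")
    if not config.base_url.startswith(("http://", "https://")):
        raise RemoteSearchError(f"malformed endpoint: {config.base_url!r}")

    cache_key = f"{term}|{_dt.date.today().isoformat()}"
    cache: dict = {}
    if config.cache_path and Path(config.cache_path).exists():
        cache = json.loads(Path(config.cache_path).read_text())
        if cache_key in cache:
            payload = cache[cache_key]
            return SearchOutcome(
                term=term,
                result_ids=tuple(payload["ids"][:top_n]),
                total_hits=int(payload["count"]),
                truncated_at=top_n,
            )

    query = f'"{term}"{config.field_tag}'
    params = {"db": "pubmed", "term": query, "retmax": str(top_n), "retmode": "json"}
    if config.api_key:
        params["api_key"] = config.api_key
    url = f"{config.base_url}?{urllib.parse.urlencode(params)}"

    last_err: Exception | None = None
    for attempt in range(config.max_retries):
        try:
            with urllib.request.urlopen(url, timeout=30) as resp:
                data = json.loads(resp.read().decode("utf-8"))
            result = data["esearchresult"]
            ids = list(dict.fromkeys(result.get("idlist", [])))
            count = int(result.get("count", len(ids)))
            if config.cache_path:
                cache[cache_key] = {"ids": ids, "count": count}
                Path(config.cache_path).write_text(json.dumps(cache, sort_keys=True))
            return SearchOutcome(
                term=term, result_ids=tuple(ids[:top_n]), total_hits=count, truncated_at=top_n
            )
        except Exception as exc:  # throttle / transient HTTP failures
            last_err = exc
            time.sleep(max(1.0 / config.rate_limit_per_s, 0.5) * (attempt + 1))
    raise RemoteSearchError(f"remote search failed after {config.max_retries} retries: {last_err}")
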