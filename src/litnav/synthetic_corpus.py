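"""Synthetic corpora with the statistical structure the method assumes.

The generator emulates the situation the benchmark probes: a corpus of
topic-clustered papers where each paper carries a rare *signature phrase*
in its title/abstract, papers cite within their topic, and a citing paper's
body re-uses the signature phrases of the papers it cites (controlled by
``phrase_share_prob``). Single-word background vocabulary follows a
deterministic Zipf law spanning the SPECIFIC/BROAD bins, while signature
phrases receive background counts below 100 so they land in the RARE bin.

Under those conditions a paper's top-ranked rare phrases include the
signatures of its cited papers, a quoted search for such a signature
retrieves the cited paper, and the term comes out CV-D — the signal the
end-to-end tests look for. Setting ``phrase_share_prob = 0`` removes the
signal, and :func:`shuffle_citations` destroys the citation graph while
keeping all text, giving the chance-validation baseline.

Documents are plain text, but built exclusively from vocabulary whose tag
is known by construction; each bundle ships a lexicon tagger over that
vocabulary, so extraction tests exercise the chunker without depending on
tagging heuristics. All randomness flows from the single seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

from litnav.corpus_model import (
    AuthorName,
    BackgroundCounts,
    Corpus,
    DocumentRecord,
    write_background_tsv,
    write_corpus_jsonl,
)
from litnav.tagging import RuleBasedTagger, Tagger

__all__ = ["GeneratorParams", "SyntheticBundle", "generate", "shuffle_citations", "write_bundle"]

_CONSONANTS = "bcdfghjklmnpqrstvz"
_VOWELS = "aeiou"


def _word(rng: np.random.Generator, n_syllables: int = 3) -> str:
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syllables)
    )


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic study conditions.

    Defaults describe a small topic-coherent corpus: 60 papers in 6 topics,
    each paper with its own rare signature phrase, 5-10 within-topic
    citations, and certain (probability 1) sharing of cited signatures into
    the citing paper's body.
    """

    n_papers: int = 60
    n_topics: int = 6
    vocab_size: int = 400
    title_vocab_size: int = 3000
    zipf_exponent: float = 1.1
    signature_phrases_per_topic: int = 10
    signature_doc_count_range: tuple[int, int] = (3, 6)
    within_topic_citation_prob: float = 0.9
    citations_per_paper_range: tuple[int, int] = (5, 10)
    phrase_share_prob: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_topic_citation_prob", "phrase_share_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        for name in ("signature_doc_count_range", "citations_per_paper_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be a non-empty positive range")
        if self.citations_per_paper_range[1] > self.n_papers - 1:
            raise ValueError("citations_per_paper_range exceeds available papers")
        if self.vocab_size < self.n_topics * self.signature_phrases_per_topic:
            raise ValueError("vocab_size must be >= n_topics * signature_phrases_per_topic")
        if self.n_papers < self.n_topics:
            raise ValueError("need at least one paper per topic")


@dataclass
class SyntheticBundle:
    """A generated corpus plus everything needed to run and score the pipeline."""

    corpus: Corpus
    background: BackgroundCounts
    tagger: Tagger
    truth: dict[str, dict] = field(default_factory=dict)  # paper_id -> planted facts
    params: GeneratorParams | None = None

    def cited_author_lists(self) -> dict[str, list[AuthorName]]:
        return {rec.doc_id: list(rec.authors) for rec in self.corpus}


def _sentences(tokens: list[str], rng: np.random.Generator, words_per_sentence: int = 8) -> str:
    out, i = [], 0
    while i < len(tokens):
        n = int(rng.integers(words_per_sentence - 2, words_per_sentence + 3))
        chunk = tokens[i : i + n]
        i += n
        out.append(" ".join(chunk).capitalize() + ".")
    return " ".join(out)


def generate(params: GeneratorParams | None = None) -> SyntheticBundle:
    """Generate a deterministic synthetic bundle from ``params.seed``.

    Body filler comes from a Zipf-ranked body vocabulary; title/abstract
    filler from a much larger title vocabulary so that any single word
    occurs in only a handful of titles — quoted searches stay selective,
    as they are at real corpus scale.  Background counts are deterministic
    Zipf over the pooled vocabulary (rank 1 lands in the BROAD bin, the
    title vocabulary in SPECIFIC); signature phrases get counts below 100
    (RARE) unless reconfigured.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed)

    def fresh_words(n: int, seen: set[str], n_syllables: int = 3) -> list[str]:
        out: list[str] = []
        while len(out) < n:
            w = _word(rng, n_syllables)
            if w not in seen:
                seen.add(w)
                out.append(w)
        return out

    seen: set[str] = set()
    vocab = fresh_words(params.vocab_size, seen)
    title_vocab = fresh_words(params.title_vocab_size, seen)
    is_adj = rng.random(params.vocab_size) < 0.2
    background = BackgroundCounts()
    top_count = 50_000_000  # word of rank 1 sits in the BROAD bin
    for rank, w in enumerate([*vocab, *title_vocab], start=1):
        background[w] = max(1, round(top_count / rank**params.zipf_exponent))

    # signature phrases: two dedicated rare tokens per phrase, per topic
    signatures: list[list[tuple[str, str]]] = []
    for _ in range(params.n_topics):
        topic_sigs = []
        for _ in range(params.signature_phrases_per_topic):
            a, b = fresh_words(2, seen, n_syllables=4)
            topic_sigs.append((a, b))
            background[f"{a} {b}"] = int(rng.integers(0, 100))  # RARE bin
        signatures.append(topic_sigs)

    lexicon = {w: ("JJ" if adj else "NN") for w, adj in zip(vocab, is_adj)}
    for w in title_vocab:
        lexicon[w] = "NN"
    for topic_sigs in signatures:
        for a, b in topic_sigs:
            lexicon[a] = "NN"
            lexicon[b] = "NN"
    tagger = RuleBasedTagger(lexicon=lexicon)

    topic_of = [i % params.n_topics for i in range(params.n_papers)]
    sig_of = [
        signatures[topic_of[i]][(i // params.n_topics) % params.signature_phrases_per_topic]
        for i in range(params.n_papers)
    ]
    doc_ids = [str(10_000_001 + i) for i in range(params.n_papers)]
    zipf_p = np.array([1 / r**params.zipf_exponent for r in range(1, params.vocab_size + 1)])
    zipf_p /= zipf_p.sum()

    # citation graph first, so shared phrases can be planted in one pass
    cited: list[list[int]] = []
    for i in range(params.n_papers):
        lo, hi = params.citations_per_paper_range
        n_cites = int(rng.integers(lo, hi + 1))
        same_topic = [j for j in range(params.n_papers) if j != i and topic_of[j] == topic_of[i]]
        other = [j for j in range(params.n_papers) if j != i and topic_of[j] != topic_of[i]]
        chosen: list[int] = []
        for _ in range(n_cites):
            pool = same_topic if (rng.random() < params.within_topic_citation_prob and same_topic) else other
            pool = [j for j in pool if j not in chosen] or [j for j in same_topic + other if j not in chosen]
            if not pool:
                break
            chosen.append(pool[int(rng.integers(len(pool)))])
        cited.append(chosen)

    records = []
    truth: dict[str, dict] = {}
    base_date = _dt.date(2005, 1, 1)
    n_filler = min(80, params.vocab_size)
    for i in range(params.n_papers):
        sig = " ".join(sig_of[i])
        # sampled without replacement: filler words stay at document count 1,
        # so planted signatures are the only repeated rare phrases
        filler = [vocab[k] for k in rng.choice(params.vocab_size, size=n_filler, replace=False, p=zipf_p)]
        lo, hi = params.signature_doc_count_range
        own_reps = int(rng.integers(lo, hi + 1))

        shared: dict[str, int] = {}
        for j in cited[i]:
            if rng.random() < params.phrase_share_prob:
                shared[" ".join(sig_of[j])] = int(rng.integers(lo, hi + 1))

        body_tokens = list(filler)
        insert_positions = rng.integers(0, len(body_tokens) + 1, size=own_reps + sum(shared.values()))
        inserts = [sig] * own_reps + [ph for ph, reps in shared.items() for _ in range(reps)]
        for pos, phrase in sorted(zip(insert_positions.tolist(), inserts), reverse=True):
            body_tokens[pos:pos] = phrase.split()

        title_extra = [title_vocab[k] for k in rng.integers(0, params.title_vocab_size, size=2)]
        abstract_fill = [title_vocab[k] for k in rng.integers(0, params.title_vocab_size, size=12)]
        records.append(
            DocumentRecord(
                doc_id=doc_ids[i],
                title=f"{sig} {' '.join(title_extra)}".capitalize(),
                abstract=_sentences([*abstract_fill[:6], *sig.split(), *abstract_fill[6:]], rng),
                body=[_sentences(body_tokens, rng)],
                authors=[
                    AuthorName(surname=f"{_word(rng).capitalize()}{i}", initials="A"),
                    AuthorName(surname=f"{_word(rng).capitalize()}{i}", initials="B"),
                ],
                pub_date=base_date + _dt.timedelta(days=int(rng.integers(0, 2300))),
                cited_ids=[doc_ids[j] for j in cited[i]],
            )
        )
        truth[doc_ids[i]] = {
            "signature": sig,
            "topic": topic_of[i],
            "shared_signatures": sorted(shared),
            "intended_cv_d_terms": sorted(
                {" ".join(sig_of[j]) for j in cited[i] if " ".join(sig_of[j]) in shared}
            ),
        }

    return SyntheticBundle(
        corpus=Corpus(records=records, name=f"synthetic-{params.seed}"),
        background=background,
        tagger=tagger,
        truth=truth,
        params=params,
    )


def shuffle_citations(bundle: SyntheticBundle, seed: int) -> SyntheticBundle:
    """Replace each paper's citations with a uniform random sample of equal size.

    Text, authors, and dates are untouched — only the citation graph is
    destroyed, which is the null construction behind the chance-validation
    argument.
    """
    rng = np.random.default_rng(seed)
    ids = [r.doc_id for r in bundle.corpus]
    new_records = []
    for rec in bundle.corpus:
        others = [d for d in ids if d != rec.doc_id]
        sample = rng.choice(len(others), size=len(rec.cited_ids), replace=False)
        new_records.append(
            DocumentRecord(
                doc_id=rec.doc_id,
                title=rec.title,
                abstract=rec.abstract,
                body=list(rec.body),
                authors=list(rec.authors),
                pub_date=rec.pub_date,
                cited_ids=[others[k] for k in sorted(sample.tolist())],
            )
        )
    return SyntheticBundle(
        corpus=Corpus(records=new_records, name=bundle.corpus.name + "-shuffled"),
        background=bundle.background,
        tagger=bundle.tagger,
        truth=bundle.truth,
        params=bundle.params,
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> None:
    """Write corpus JSON-lines, background TSV, and truth JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_corpus_jsonl(bundle.corpus, out / "corpus.jsonl")
    write_background_tsv(bundle.background, out / "background.tsv")
    (out / "truth.json").write_text(json.dumps(bundle.truth, indent=1, sort_keys=True))
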