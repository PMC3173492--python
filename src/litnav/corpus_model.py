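"""Document records, citation tables, author names, and background phrase counts.

A :class:`Corpus` is the unit every downstream stage operates on: a set of
:class:`DocumentRecord` objects (title, abstract, body prose, authors,
publication date, and the author-supplied citation ids retrieved from the
article record).  Background counts — the web-scale occurrence counts used
as the rarity denominator when ranking phrases — live in
:class:`BackgroundCounts`, a total mapping: any phrase not in the table has
count 0.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import unicodedata
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from lxml import etree

__all__ = [
    "AuthorName",
    "BackgroundCounts",
    "Corpus",
    "DocumentRecord",
    "filter_min_citations",
    "parse_author_string",
    "read_citation_table",
    "read_jats",
    "read_plaintext",
    "read_background_tsv",
    "write_background_tsv",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
]


def _strip_diacritics(text: str) -> str:
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


@dataclass(frozen=True)
class AuthorName:
    """An author identity reduced to the key available in citation metadata.

    Normalization (case-folded, diacritics-stripped surname + first initial)
    is deliberately coarse: it is the richest key the citation tables carry,
    and it is what makes the same-author / different-author distinction
    reproducible.
    """

    surname: str
    initials: str = ""

    def __post_init__(self) -> None:
        if not self.normalized_surname:
            raise ValueError(f"author surname empty after normalization: {self!r}")

    @property
    def normalized_surname(self) -> str:
        return _strip_diacritics(self.surname).casefold().strip()

    @property
    def key(self) -> tuple[str, str]:
        """(surname, first initial) — the identity used for CV-S / CV-D."""
        initial = _strip_diacritics(self.initials).casefold().strip()[:1]
        return (self.normalized_surname, initial)


def parse_author_string(text: str) -> list[AuthorName]:
    """Parse a semicolon-separated ``"Surname Initials; Surname Initials"`` list."""
    authors = []
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        pieces = part.rsplit(None, 1)
        if len(pieces) == 2 and pieces[1].replace("-", "").replace(".", "").isalpha() and len(
            pieces[1].replace(".", "")
        ) <= 3:
            surname, initials = pieces[0], pieces[1].replace(".", "")
        else:
            surname, initials = part, ""
        authors.append(AuthorName(surname=surname, initials=initials))
    return authors


@dataclass
class DocumentRecord:
    """One paper: identity, searchable text, authors, and author-supplied citations."""

    doc_id: str
    title: str = ""
    abstract: str = ""
    body: list[str] = field(default_factory=list)
    authors: list[AuthorName] = field(default_factory=list)
    pub_date: _dt.date | None = None
    cited_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        seen: set[str] = set()
        deduped = []
        for cid in self.cited_ids:
            if cid == self.doc_id:
                continue  # self-listing never counts as a citation
            if cid not in seen:
                seen.add(cid)
                deduped.append(cid)
        self.cited_ids = deduped

    @property
    def text_blocks(self) -> list[str]:
        """Title, abstract, and body prose — the text phrases are extracted from."""
        blocks = [self.title, self.abstract, *self.body]
        return [b for b in blocks if b]

    def author_keys(self) -> frozenset[tuple[str, str]]:
        return frozenset(a.key for a in self.authors)

    def to_json(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "title": self.title,
            "abstract": self.abstract,
            "body": self.body,
            "authors": [{"surname": a.surname, "initials": a.initials} for a in self.authors],
            "pub_date": self.pub_date.isoformat() if self.pub_date else None,
            "cited_ids": self.cited_ids,
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "DocumentRecord":
        return cls(
            doc_id=obj["doc_id"],
            title=obj.get("title", ""),
            abstract=obj.get("abstract", ""),
            body=list(obj.get("body", [])),
            authors=[AuthorName(a["surname"], a.get("initials", "")) for a in obj.get("authors", [])],
            pub_date=_dt.date.fromisoformat(obj["pub_date"]) if obj.get("pub_date") else None,
            cited_ids=list(obj.get("cited_ids", [])),
        )


class BackgroundCounts:
    """Total mapping phrase -> non-negative occurrence count in a reference corpus.

    Originally these were web search hit counts; any large-corpus count table
    with the same Zipf-like shape serves the same role.  Lookup of an absent
    phrase returns 0, so the mapping is total.
    """

    def __init__(self, counts: Mapping[str, int] | None = None) -> None:
        self._counts: dict[str, int] = {}
        if counts:
            for phrase, count in counts.items():
                self[phrase] = count

    @staticmethod
    def _canon(phrase: str) -> str:
        return " ".join(phrase.casefold().split())

    def __setitem__(self, phrase: str, count: int) -> None:
        if count < 0:
            raise ValueError(f"negative background count for {phrase!r}: {count}")
        self._counts[self._canon(phrase)] = int(count)

    def __getitem__(self, phrase: str) -> int:
        return self._counts.get(self._canon(phrase), 0)

    def __call__(self, phrase: str) -> int:
        """Provider contract: a total callable phrase -> count."""
        return self[phrase]

    def __len__(self) -> int:
        return len(self._counts)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def items(self):
        return self._counts.items()


@dataclass
class Corpus:
    """A named collection of documents with unique ids."""

    records: list[DocumentRecord]
    name: str = "corpus"

    def __post_init__(self) -> None:
        ids = [r.doc_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate doc_ids in corpus: {dupes[:5]}")
        self._by_id = {r.doc_id: r for r in self.records}

    @property
    def size(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[DocumentRecord]:
        return iter(self.records)

    def __getitem__(self, doc_id: str) -> DocumentRecord:
        return self._by_id[doc_id]

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._by_id


def read_plaintext(path: str | Path, doc_id: str) -> DocumentRecord:
    """Read a plain-text article; paragraphs are blank-line separated blocks.

    The first non-empty line is taken as the title.  Authors and citations
    stay empty until joined from a citation table.
    """
    text = Path(path).read_text(encoding="utf-8")
    if not text.strip():
        raise ValueError(f"empty document: {path}")
    blocks = [" ".join(b.split()) for b in text.split("\n\n")]
    blocks = [b for b in blocks if b]
    title = blocks[0].splitlines()[0] if blocks else ""
    return DocumentRecord(doc_id=doc_id, title=title, body=blocks)


_JATS_PMID_XPATH = './/pub-id[@pub-id-type="pmid"]'


def read_jats(path: str | Path) -> DocumentRecord:
    """Read a PMC-style JATS NXML article.

    Extracts title, abstract, body paragraphs, authors, and the citation
    PMIDs from the reference list.  The reference-list *text* is excluded
    from the body — reference strings would inflate phrase counts with
    cited-paper titles — and references without a tagged PMID are dropped,
    since overlap is computed on PubMed-style ids.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()

    def text_of(elem) -> str:
        return " ".join("".join(elem.itertext()).split()) if elem is not None else ""

    doc_id = ""
    for aid in root.iter("article-id"):
        if aid.get("pub-id-type") in ("pmid", "pmc"):
            doc_id = text_of(aid)
            if aid.get("pub-id-type") == "pmid":
                break
    title = text_of(root.find(".//front//article-title"))
    abstract = text_of(root.find(".//front//abstract"))

    authors = []
    for contrib in root.findall('.//front//contrib[@contrib-type="author"]'):
        surname = text_of(contrib.find(".//surname"))
        given = text_of(contrib.find(".//given-names"))
        if surname:
            initials = "".join(w[0] for w in given.split()) if given else ""
            authors.append(AuthorName(surname=surname, initials=initials))

    pub_date = None
    for pd in root.findall(".//front//pub-date"):
        year = text_of(pd.find("year"))
        if year:
            month = text_of(pd.find("month")) or "1"
            day = text_of(pd.find("day")) or "1"
            try:
                pub_date = _dt.date(int(year), int(month), int(day))
            except ValueError:
                pub_date = _dt.date(int(year), 1, 1)
            break

    body_elem = root.find(".//body")
    body = []
    if body_elem is None:
        warnings.warn(f"JATS article {path} has no <body>; partial record", stacklevel=2)
    else:
        body = [text_of(p) for p in body_elem.iter("p") if text_of(p)]

    cited_ids = []
    for ref_list in root.findall(".//back//ref-list"):
        for pmid in ref_list.findall(_JATS_PMID_XPATH):
            pid = text_of(pmid)
            if pid:
                cited_ids.append(pid)

    if not doc_id:
        raise ValueError(f"JATS article {path} carries no pmid/pmc article-id")
    return DocumentRecord(
        doc_id=doc_id,
        title=title,
        abstract=abstract,
        body=body,
        authors=authors,
        pub_date=pub_date,
        cited_ids=cited_ids,
    )


def read_citation_table(path: str | Path) -> dict[str, tuple[list[str], list[list[AuthorName]]]]:
    """Read a delimited citation table into ``{paper_id: (cited_ids, author lists)}``.

    Expected columns: ``paper_id``, ``cited_id``, ``cited_authors`` (a
    semicolon-separated "Surname Initials" list, possibly empty).  Duplicate
    (paper_id, cited_id) rows are collapsed with a warning.
    """
    path = Path(path)
    delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    mapping: dict[str, tuple[list[str], list[list[AuthorName]]]] = {}
    seen: set[tuple[str, str]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        required = {"paper_id", "cited_id", "cited_authors"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"citation table {path} must have columns {sorted(required)}, got {reader.fieldnames}"
            )
        for row in reader:
            key = (row["paper_id"], row["cited_id"])
            if key in seen:
                warnings.warn(f"duplicate citation row collapsed: {key}", stacklevel=2)
                continue
            seen.add(key)
            ids, author_lists = mapping.setdefault(row["paper_id"], ([], []))
            ids.append(row["cited_id"])
            author_lists.append(parse_author_string(row.get("cited_authors") or ""))
    return mapping


def filter_min_citations(corpus: Corpus, min_citations: int) -> Corpus:
    """Keep only papers with at least ``min_citations`` author-supplied citations.

    The citation-validation benchmark is meaningless for papers with too few
    citations to recover, hence the sample filter (default 5 upstream).
    """
    if min_citations < 0:
        raise ValueError("min_citations must be >= 0")
    kept = [r for r in corpus.records if len(r.cited_ids) >= min_citations]
    return Corpus(records=kept, name=corpus.name)


def read_background_tsv(path: str | Path) -> BackgroundCounts:
    """Read a 2-column ``phrase<TAB>count`` table."""
    counts = BackgroundCounts()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                phrase, count = line.split("\t")
                counts[phrase] = int(count)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad background-count row {line!r}") from exc
    return counts


def write_background_tsv(counts: BackgroundCounts, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for phrase, count in sorted(counts.items()):
            fh.write(f"{phrase}\t{count}\n")


def write_corpus_jsonl(corpus: Corpus, path: str | Path) -> None:
    """One DocumentRecord per line, JSON-encoded."""
    with open(path, "w", encoding="utf-8") as fh:
        for record in corpus:
            fh.write(json.dumps(record.to_json(), sort_keys=True) + "\n")


def read_corpus_jsonl(path: str | Path, name: str | None = None) -> Corpus:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                records.append(DocumentRecord.from_json(json.loads(line)))
    return Corpus(records=records, name=name or Path(path).stem)
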