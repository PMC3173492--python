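"""Citation validation: overlap, CV-S/CV-D classification, aggregation, chance model.

A candidate list (the top-20 results of a quoted phrase search, or an
externally supplied "related citations" list) *overlaps* when it contains
at least one of the paper's author-supplied citations. An overlapping list
is *citation-validated*: CV-D when some validating citation was written by
an entirely different author set than the paper, CV-S when the validating
citations all share an author with the paper (the paper's own record in
the results — a self-hit — also counts as CV-S). CV-D takes precedence,
so validated terms partition into D and S.

The chance model: if a search's top k results were k independent uniform
draws from a corpus of N documents, a paper with C citations would be
validated with probability 1 − (1 − C/N)^k ≈ kC/N — under a PubMed-scale
N of 18 million and C ≤ 100 that is below 1 in 5000 searches, so observed
validation is very unlikely to be chance.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from litnav.corpus_model import AuthorName, DocumentRecord
from litnav.search_backend import SearchOutcome

__all__ = [
    "Classification",
    "ValidationRecord",
    "PaperReport",
    "CorpusSummary",
    "NullModelParams",
    "compute_overlap",
    "classify_validation",
    "evaluate_terms",
    "evaluate_candidate_list",
    "aggregate",
    "random_cv_probability",
    "simulate_chance_validation",
    "RELATED_CITATIONS_LABEL",
]

RELATED_CITATIONS_LABEL = "related_citations"


class Classification(enum.Enum):
    NOT_CV = "not_cv"
    CV_S = "cv_s"
    CV_D = "cv_d"


@dataclass(frozen=True)
class ValidationRecord:
    """Per-query validation outcome."""

    term: str
    result_ids: tuple[str, ...]
    overlapping_ids: tuple[str, ...]  # result ∩ citations, result order
    self_hit: bool
    classification: Classification
    non_overlap_count: int  # results that are neither validating citations nor self-hits
    total_hits: int

    def to_json(self) -> dict:
        return {
            "term": self.term,
            "result_ids": list(self.result_ids),
            "overlapping_ids": list(self.overlapping_ids),
            "self_hit": self.self_hit,
            "classification": self.classification.value,
            "non_overlap_count": self.non_overlap_count,
            "total_hits": self.total_hits,
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "ValidationRecord":
        return cls(
            term=obj["term"],
            result_ids=tuple(obj["result_ids"]),
            overlapping_ids=tuple(obj["overlapping_ids"]),
            self_hit=obj["self_hit"],
            classification=Classification(obj["classification"]),
            non_overlap_count=obj["non_overlap_count"],
            total_hits=obj["total_hits"],
        )


def compute_overlap(
    result_ids: Sequence[str], cited_ids: Iterable[str], paper_id: str
) -> tuple[tuple[str, ...], bool]:
    """Intersect a result list with the paper's citations, preserving result order.

    Returns ``(overlapping_ids, self_hit)``; the paper's own id in the
    results is flagged separately, never counted among the overlap.
    """
    cited = set(cited_ids)
    overlapping = tuple(r for r in result_ids if r in cited and r != paper_id)
    return overlapping, paper_id in result_ids


AuthorKeys = frozenset


def _author_keys(authors: Iterable[AuthorName]) -> frozenset:
    return frozenset(a.key for a in authors)


def classify_validation(
    overlapping_ids: Sequence[str],
    self_hit: bool,
    paper_authors: Iterable[AuthorName],
    cited_author_lists: Mapping[str, Sequence[AuthorName]] | None = None,
) -> Classification:
    """Classify one candidate list as NOT_CV, CV_S, or CV_D.

    CV_D requires at least one overlapping citation whose (normalized)
    author set is disjoint from the paper's; it takes precedence over CV_S
    so the two form a partition of validated lists. An overlapping citation
    with no author data is conservatively treated as shared-author.
    """
    if not overlapping_ids and not self_hit:
        return Classification.NOT_CV
    paper_keys = _author_keys(paper_authors)
    cited_author_lists = cited_author_lists or {}
    for cid in overlapping_ids:
        authors = cited_author_lists.get(cid)
        if not authors:
            warnings.warn(
                f"no author data for overlapping citation {cid}; treating as shared-author",
                stacklevel=2,
            )
            continue
        if _author_keys(authors).isdisjoint(paper_keys):
            return Classification.CV_D
    return Classification.CV_S


@dataclass
class PaperReport:
    """Roll-up of a paper's validation records."""

    paper_id: str
    records: list[ValidationRecord] = field(default_factory=list)
    label: str = "search_terms"

    @property
    def n_cv_d_terms(self) -> int:
        return sum(1 for r in self.records if r.classification is Classification.CV_D)

    @property
    def n_cv_s_terms(self) -> int:
        return sum(1 for r in self.records if r.classification is Classification.CV_S)

    @property
    def n_validated_terms(self) -> int:
        return self.n_cv_d_terms + self.n_cv_s_terms

    @property
    def unique_validating_citations(self) -> int:
        """Distinct ids validating any term, pooling D and S (self-hits included)."""
        ids: set[str] = set()
        for r in self.records:
            ids.update(r.overlapping_ids)
            if r.self_hit:
                ids.add(f"self:{self.paper_id}")
        return len(ids)

    @property
    def unique_cv_d_validators(self) -> int:
        """Distinct cited ids overlapping CV-D terms; self-hits never counted."""
        ids: set[str] = set()
        for r in self.records:
            if r.classification is Classification.CV_D:
                ids.update(r.overlapping_ids)
        return len(ids)

    def _cv_non_overlap_counts(self) -> list[int]:
        return [
            r.non_overlap_count
            for r in self.records
            if r.classification is not Classification.NOT_CV
        ]

    @property
    def n_terms_lt5(self) -> int:
        return sum(1 for c in self._cv_non_overlap_counts() if c < 5)

    @property
    def n_terms_lt20(self) -> int:
        return sum(1 for c in self._cv_non_overlap_counts() if c < 20)

    @property
    def n_terms_gt20(self) -> int:
        return sum(1 for c in self._cv_non_overlap_counts() if c > 20)

    def n_terms_nonoverlap_gt(self, threshold: int) -> int:
        """Terms (validated or not) with more than ``threshold`` non-overlapping results."""
        return sum(1 for r in self.records if r.non_overlap_count > threshold)

    def to_json(self) -> dict:
        return {
            "paper_id": self.paper_id,
            "label": self.label,
            "records": [r.to_json() for r in self.records],
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "PaperReport":
        return cls(
            paper_id=obj["paper_id"],
            label=obj.get("label", "search_terms"),
            records=[ValidationRecord.from_json(r) for r in obj["records"]],
        )


def _make_record(
    term: str,
    result_ids: Sequence[str],
    total_hits: int,
    paper: DocumentRecord,
    cited_author_lists: Mapping[str, Sequence[AuthorName]] | None,
) -> ValidationRecord:
    overlapping, self_hit = compute_overlap(result_ids, paper.cited_ids, paper.doc_id)
    classification = classify_validation(
        overlapping, self_hit, paper.authors, cited_author_lists
    )
    # the <5/<20/>20 buckets need the untruncated count net of validating
    # citations and self-hits; truncated lists alone cannot distinguish >20
    non_overlap = max(0, total_hits - len(overlapping) - (1 if self_hit else 0))
    return ValidationRecord(
        term=term,
        result_ids=tuple(result_ids),
        overlapping_ids=overlapping,
        self_hit=self_hit,
        classification=classification,
        non_overlap_count=non_overlap,
        total_hits=total_hits,
    )


def evaluate_terms(
    paper: DocumentRecord,
    outcomes: Iterable[SearchOutcome],
    cited_author_lists: Mapping[str, Sequence[AuthorName]] | None = None,
) -> PaperReport:
    """Validate each search term's result list against the paper's citations."""
    records = [
        _make_record(o.term, o.result_ids, o.total_hits, paper, cited_author_lists)
        for o in outcomes
    ]
    return PaperReport(paper_id=paper.doc_id, records=records)


def evaluate_candidate_list(
    paper: DocumentRecord,
    candidate_ids: Sequence[str],
    cited_author_lists: Mapping[str, Sequence[AuthorName]] | None = None,
    label: str = RELATED_CITATIONS_LABEL,
    top_n: int = 20,
) -> PaperReport:
    """Apply the same metrics to one externally supplied candidate list.

    Used for the related-citations comparison column; lists longer than
    ``top_n`` are truncated with a warning.
    """
    candidate_ids = list(dict.fromkeys(candidate_ids))
    total = len(candidate_ids)
    if total > top_n:
        warnings.warn(f"candidate list truncated from {total} to {top_n}", stacklevel=2)
        candidate_ids = candidate_ids[:top_n]
    record = _make_record(label, candidate_ids, total, paper, cited_author_lists)
    return PaperReport(paper_id=paper.doc_id, records=[record], label=label)


def _wald_ci_pct(k: int, n: int) -> tuple[float, float, float]:
    """Point estimate and outward-rounded 95% Wald CI, all in percent."""
    p = k / n
    half = 1.96 * math.sqrt(p * (1 - p) / n)
    lo = max(0.0, math.floor((p - half) * 100))
    hi = min(100.0, math.ceil((p + half) * 100))
    return p * 100, lo, hi


def _mean_sd(values: Sequence[int]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


@dataclass(frozen=True)
class CorpusSummary:
    """Corpus-level benchmark summary (one column of the comparison table)."""

    n_papers: int
    pct_papers_cv_d: float
    ci_cv_d: tuple[float, float]
    pct_papers_cv_s: float
    ci_cv_s: tuple[float, float]
    mean_cv_d_terms: float
    sd_cv_d_terms: float
    mean_cv_s_terms: float
    sd_cv_s_terms: float
    mean_unique_validating: float
    sd_unique_validating: float
    pct_with_term_lt5: float
    ci_lt5: tuple[float, float]
    pct_with_term_lt20: float
    ci_lt20: tuple[float, float]
    pct_with_term_gt20: float
    ci_gt20: tuple[float, float]

    def to_json(self) -> dict:
        return {
            "n_papers": self.n_papers,
            "pct_papers_cv_d": self.pct_papers_cv_d,
            "ci_cv_d": list(self.ci_cv_d),
            "pct_papers_cv_s": self.pct_papers_cv_s,
            "ci_cv_s": list(self.ci_cv_s),
            "mean_cv_d_terms": self.mean_cv_d_terms,
            "sd_cv_d_terms": self.sd_cv_d_terms,
            "mean_cv_s_terms": self.mean_cv_s_terms,
            "sd_cv_s_terms": self.sd_cv_s_terms,
            "mean_unique_validating": self.mean_unique_validating,
            "sd_unique_validating": self.sd_unique_validating,
            "pct_with_term_lt5": self.pct_with_term_lt5,
            "ci_lt5": list(self.ci_lt5),
            "pct_with_term_lt20": self.pct_with_term_lt20,
            "ci_lt20": list(self.ci_lt20),
            "pct_with_term_gt20": self.pct_with_term_gt20,
            "ci_gt20": list(self.ci_gt20),
        }

    def to_rows(self) -> list[tuple[str, str]]:
        """Table rendering: (metric, value) rows."""

        def pct(p, ci):
            return f"{p:.0f}% ({ci[0]:.0f}-{ci[1]:.0f}% at 95% confidence)"

        def ms(m, s):
            return f"{m:.1f} (+/-{s:.1f} standard deviation)"

        return [
            ("Papers validated by citations from different authors (CV-D)", pct(self.pct_papers_cv_d, self.ci_cv_d)),
            ("Number of search terms that are CV-D (mean, sd)", ms(self.mean_cv_d_terms, self.sd_cv_d_terms)),
            ("Papers validated by citations from the original authors (CV-S)", pct(self.pct_papers_cv_s, self.ci_cv_s)),
            ("Number of search terms that are CV-S (mean, sd)", ms(self.mean_cv_s_terms, self.sd_cv_s_terms)),
            ("Unique validating citations (mean, sd)", ms(self.mean_unique_validating, self.sd_unique_validating)),
            ("Papers with a CV term with <5 results (excluding validating citations)", pct(self.pct_with_term_lt5, self.ci_lt5)),
            ("Papers with a CV term with <20 results (excluding validating citations)", pct(self.pct_with_term_lt20, self.ci_lt20)),
            ("Papers with a CV term with >20 results (excluding validating citations)", pct(self.pct_with_term_gt20, self.ci_gt20)),
        ]


def aggregate(reports: Sequence[PaperReport]) -> CorpusSummary:
    """Summarize per-paper reports: CV percentages with 95% Wald CIs, means, sample SDs.

    A pure function of the reports — re-aggregating reports reloaded from
    disk reproduces the summary bit for bit.
    """
    if not reports:
        raise ValueError("cannot aggregate zero reports")
    n = len(reports)
    cv_d = sum(1 for r in reports if r.n_cv_d_terms > 0)
    cv_s = sum(1 for r in reports if r.n_cv_s_terms > 0)
    lt5 = sum(1 for r in reports if r.n_terms_lt5 > 0)
    lt20 = sum(1 for r in reports if r.n_terms_lt20 > 0)
    gt20 = sum(1 for r in reports if r.n_terms_gt20 > 0)

    p_d, lo_d, hi_d = _wald_ci_pct(cv_d, n)
    p_s, lo_s, hi_s = _wald_ci_pct(cv_s, n)
    p5, lo5, hi5 = _wald_ci_pct(lt5, n)
    p20, lo20, hi20 = _wald_ci_pct(lt20, n)
    pg, log_, hig = _wald_ci_pct(gt20, n)
    m_d, s_d = _mean_sd([r.n_cv_d_terms for r in reports])
    m_s, s_s = _mean_sd([r.n_cv_s_terms for r in reports])
    m_u, s_u = _mean_sd([r.unique_validating_citations for r in reports])

    return CorpusSummary(
        n_papers=n,
        pct_papers_cv_d=p_d,
        ci_cv_d=(lo_d, hi_d),
        pct_papers_cv_s=p_s,
        ci_cv_s=(lo_s, hi_s),
        mean_cv_d_terms=m_d,
        sd_cv_d_terms=s_d,
        mean_cv_s_terms=m_s,
        sd_cv_s_terms=s_s,
        mean_unique_validating=m_u,
        sd_unique_validating=s_u,
        pct_with_term_lt5=p5,
        ci_lt5=(lo5, hi5),
        pct_with_term_lt20=p20,
        ci_lt20=(lo20, hi20),
        pct_with_term_gt20=pg,
        ci_gt20=(log_, hig),
    )


@dataclass(frozen=True)
class NullModelParams:
    """Parameters of the chance-validation model: C citations, corpus size N, k results."""

    c: int
    n: int
    k: int = 20

    def __post_init__(self) -> None:
        if self.n < 1 or not 0 <= self.c <= self.n or self.k < 1:
            raise ValueError(f"invalid null-model parameters: {self}")

    @property
    def probability(self) -> float:
        return random_cv_probability(self.c, self.n, self.k)

    @property
    def linear_approximation(self) -> float:
        """First-order approximation kC/N, accurate when kC/N is small."""
        return self.k * self.c / self.n


def random_cv_probability(c: int, n: int, k: int = 20) -> float:
    """P(at least one of C cited docs among k independent uniform draws from N).

    1 − (1 − C/N)^k; the probability that a *random* search would appear
    citation-validated. For C = 100, N = 18 million, k = 20 this is about
    1.1e-4 — under 1 in 5000 searches.
    """
    if n < 1:
        raise ValueError("corpus size must be >= 1")
    if not 0 <= c <= n:
        raise ValueError(f"need 0 <= C <= N, got C={c}, N={n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 - (1.0 - c / n) ** k


def simulate_chance_validation(
    n_docs: int,
    n_citations: int,
    k: int = 20,
    n_searches: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo check of the chance model on a shuffled-citation corpus.

    Each simulated paper's citation list is ``n_citations`` ids drawn
    uniformly without replacement; each search returns ``k`` uniform draws.
    Returns the empirical fraction of searches with non-empty overlap
    (computed through :func:`compute_overlap`).
    """
    rng = np.random.default_rng(seed)
    ids = np.array([str(i) for i in range(n_docs)], dtype=object)
    validated = 0
    for _ in range(n_searches):
        cited = ids[rng.choice(n_docs, size=n_citations, replace=False)]
        results = ids[rng.choice(n_docs, size=k, replace=False)]
        overlap, _ = compute_overlap(list(results), cited, paper_id="-1")
        if overlap:
            validated += 1
    return validated / n_searches
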