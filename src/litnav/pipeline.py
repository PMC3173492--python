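"""End-to-end orchestration: extract → count → rank → select → search → validate → aggregate."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from litnav.citation_validation import (
    CorpusSummary,
    PaperReport,
    aggregate,
    evaluate_terms,
)
from litnav.corpus_model import (
    AuthorName,
    BackgroundCounts,
    Corpus,
    DocumentRecord,
    filter_min_citations,
)
from litnav.phrase_extraction import attach_background, count_phrases
from litnav.phrase_ranking import (
    Bin,
    RankedPhrase,
    RankingMethod,
    rank_phrases,
    select_terms,
)
from litnav.search_backend import PhraseIndex, build_index, phrase_search
from litnav.tagging import Tagger

__all__ = ["RunConfig", "run_paper", "run_corpus", "histogram_data"]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the benchmark's fixed constants.

    20 terms per bin, top-20 result lists, papers with ≥5 citations, bin
    thresholds 100 / 10,000,000, median (τ = 0.5) quantile regression.
    """

    tagger: Tagger | None = None
    max_phrase_len: int = 5
    tau: float = 0.5
    method: RankingMethod = RankingMethod.RESIDUAL
    per_bin: int = 20
    bins: tuple[Bin, ...] = (Bin.SPECIFIC, Bin.RARE)
    top_n: int = 20
    min_citations: int = 5
    include_single_adjectives: bool = True
    seed: int = 0


def run_paper(
    doc: DocumentRecord,
    index: PhraseIndex,
    background: BackgroundCounts,
    cited_author_lists: Mapping[str, Sequence[AuthorName]] | None = None,
    config: RunConfig | None = None,
) -> tuple[list[RankedPhrase], list, PaperReport]:
    """Run the full method on one paper against an indexed corpus.

    Returns (ranked phrases, search outcomes, validation report). A paper
    with no extractable noun/adjective tokens yields a zero-term report.
    """
    config = config or RunConfig()
    try:
        stats = count_phrases(doc, config.tagger, config.max_phrase_len)
    except ValueError:
        stats = []
    if not stats:
        return [], [], PaperReport(paper_id=doc.doc_id, records=[])
    attach_background(stats, background)
    ranked = rank_phrases(stats, method=config.method, tau=config.tau)
    terms = select_terms(
        ranked,
        per_bin=config.per_bin,
        bins=config.bins,
        include_single_adjectives=config.include_single_adjectives,
    )
    outcomes = [phrase_search(index, t.term, config.top_n) for t in terms]
    report = evaluate_terms(doc, outcomes, cited_author_lists)
    return ranked, outcomes, report


def run_corpus(
    corpus: Corpus,
    background: BackgroundCounts,
    cited_author_lists: Mapping[str, Sequence[AuthorName]] | None = None,
    config: RunConfig | None = None,
) -> tuple[CorpusSummary, list[PaperReport]]:
    """Run the benchmark over every paper passing the citation filter.

    The search index covers the *whole* corpus (a paper's searches can hit
    any document, including itself); only evaluation is restricted to
    papers with enough citations to validate against.
    """
    config = config or RunConfig()
    evaluable = filter_min_citations(corpus, config.min_citations)
    if len(evaluable) == 0:
        raise ValueError("no papers pass the citation filter")
    index = build_index(corpus)
    reports = []
    for doc in evaluable:
        _, _, report = run_paper(doc, index, background, cited_author_lists, config)
        reports.append(report)
    return aggregate(reports), reports


def histogram_data(reports: Sequence[PaperReport]) -> dict[str, list[int]]:
    """Per-paper count distributions behind the summary table.

    Keys: CV-D terms per paper, unique validating citations per paper, and
    the number of terms with more than 10 / more than 100 non-overlapping
    results. Each list has one entry per paper, so each histogram sums to
    the paper count.
    """
    return {
        "cv_d_terms_per_paper": [r.n_cv_d_terms for r in reports],
        "validating_citations_per_paper": [r.unique_validating_citations for r in reports],
        "terms_gt10_nonoverlap_per_paper": [r.n_terms_nonoverlap_gt(10) for r in reports],
        "terms_gt100_nonoverlap_per_paper": [r.n_terms_nonoverlap_gt(100) for r in reports],
    }


def write_reports(reports: Sequence[PaperReport], out_dir: str | Path) -> Path:
    """One JSON file per paper under ``out_dir``; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for r in reports:
        (out / f"{r.paper_id}.json").write_text(json.dumps(r.to_json(), indent=1, sort_keys=True))
    return out


def read_reports(report_dir: str | Path) -> list[PaperReport]:
    reports = []
    for path in sorted(Path(report_dir).glob("*.json")):
        reports.append(PaperReport.from_json(json.loads(path.read_text())))
    return reports
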