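"""Packaged worked-example fixture: prostate-cancer AGR2 paper, PMID 21144054 (PMC3009682).

The fixture reproduces the published worked example for "Differential
expression of anterior gradient gene AGR2 in prostate cancer": the sixteen
citation-validated search terms with their result counts, validating
citation ids, and D/S (different-/same-author) labels, plus the top-20
related-citations comparison with its four overlapping citations, and the
eight listed non-cited results of the "AGR2 expression" search.

Only ids and counts were published. Everything else here is a labelled
SYNTHETIC stand-in constructed to be consistent with the published labels:
author names (each citation gets authors disjoint from the paper's, as the
uniform D labels require), the filler result/citation ids that pad lists to
their published sizes (prefixes 6xx/70x/65x, outside any real id range),
and one extra non-cited result id for "AGR2 expression" (the source lists
eight of the nine).
"""

from __future__ import annotations

from dataclasses import dataclass

from litnav.corpus_model import AuthorName, DocumentRecord
from litnav.search_backend import SearchOutcome

__all__ = ["Agr2Fixture", "load_agr2_fixture", "AGR2_PASSAGE", "AGR2_TERMS"]

#: The example passage used to illustrate noun-phrase extraction.
AGR2_PASSAGE = (
    "AGR2 has been implicated in cancer pathogenesis and has been found to be "
    "up-regulated in multiple human cancers, including breast, lung, and prostate. "
    "Our study has shown that AGR2 is higher in prostate cancer cells compared to "
    "non-malignant prostatic epithelial cells at the transcript and protein levels."
)

PAPER_ID = "21144054"
PMC_ID = "PMC3009682"
N_CITATIONS = 46  # author-supplied citations on record for this paper

#: (term, published result count, D/S label, validating citation ids).
AGR2_TERMS: list[tuple[str, int, str, list[str]]] = [
    ("laevis cement gland", 4, "D", ["10095068", "9790916"]),
    ("Xenopus laevis cement gland", 4, "D", ["10095068", "9790916"]),
    ("AGR2 promotes cell", 7, "D", ["20048076", "18199544"]),
    ("AGR2", 70, "D", ["20945500"]),
    ("XAG-2", 9, "D", ["15834940", "14967811", "10095068", "9790916", "9533957"]),
    ("AGR2 expression", 15, "D", ["20048076", "18681322", "18199544", "17457305", "17455144", "16551856"]),
    ("Xenopus laevis cement", 5, "D", ["10095068", "9790916"]),
    ("gene XAG-2", 3, "D", ["9790916", "9533957"]),
    ("hAG-2", 6, "D", ["12592373", "9790916"]),
    ("cement gland gene XAG-2", 4, "D", ["10095068", "9790916", "9533957"]),
    ("gland gene XAG-2", 5, "D", ["15834940", "10095068", "9790916", "9533957"]),
    ("PIN lesions", 127, "D", ["20945500"]),
    ("laevis cement gland gene", 70, "D", ["15867376"]),
    ("levels of AGR2", 17, "D", ["20945500", "20048076", "18973922", "17694278", "17457305"]),
    ("laevis cement", 118, "D", ["15867376"]),
    ("lower levels of AGR2", 3, "S", [PAPER_ID]),
]

#: Published non-cited results of the "AGR2 expression" search (8 of the 9 listed).
AGR2_EXPRESSION_NONCITED = [
    "21454516", "21281432", "20531310", "20525379",
    "20025862", "19773444", "18829536", "9831665",
]

#: Overlapping citations in the top-20 related-citations list (different authors).
RELATED_CITATIONS_OVERLAP = ["20945500", "20048076", "18199544", "17457305"]

TOP_N = 20


def _distinct_validating_ids() -> list[str]:
    ids: list[str] = []
    for _, _, label, vids in AGR2_TERMS:
        for v in vids:
            if label == "D" and v not in ids:
                ids.append(v)
    return ids


@dataclass
class Agr2Fixture:
    paper: DocumentRecord
    outcomes: list[SearchOutcome]
    cited_author_lists: dict[str, list[AuthorName]]
    related_citations: list[str]
    labels: dict[str, str]  # term -> published D/S label


def load_agr2_fixture() -> Agr2Fixture:
    """Assemble the worked-example fixture (published ids + synthetic padding)."""
    validating = _distinct_validating_ids()
    filler_citations = [f"70000{k:03d}" for k in range(N_CITATIONS - len(validating))]
    cited_ids = validating + filler_citations

    paper = DocumentRecord(
        doc_id=PAPER_ID,
        title="Differential expression of anterior gradient gene AGR2 in prostate cancer",
        abstract="",
        body=[AGR2_PASSAGE],
        authors=[AuthorName("Synthetica", "A"), AuthorName("Syntheticb", "B")],  # synthetic
        cited_ids=cited_ids,
    )
    cited_author_lists = {
        cid: [AuthorName(f"Ref{cid}", "A")] for cid in cited_ids  # synthetic, author-disjoint
    }

    outcomes = []
    for i, (term, n_results, label, vids) in enumerate(AGR2_TERMS):
        results = list(vids)
        if term == "AGR2 expression":
            results += AGR2_EXPRESSION_NONCITED
        shown = min(n_results, TOP_N)
        k = 0
        while len(results) < shown:
            results.append(f"6{i:02d}000{k:02d}")  # synthetic filler result
            k += 1
        outcomes.append(
            SearchOutcome(term=term, result_ids=tuple(results), total_hits=n_results, truncated_at=TOP_N)
        )

    related = list(RELATED_CITATIONS_OVERLAP)
    related += [f"650000{k:02d}" for k in range(TOP_N - len(related))]

    return Agr2Fixture(
        paper=paper,
        outcomes=outcomes,
        cited_author_lists=cited_author_lists,
        related_citations=related,
        labels={term: label for term, _, label, _ in AGR2_TERMS},
    )
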