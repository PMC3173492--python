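import json

import numpy as np
import pytest

from litnav.citation_validation import (
    Classification,
    NullModelParams,
    PaperReport,
    ValidationRecord,
    aggregate,
    classify_validation,
    compute_overlap,
    evaluate_candidate_list,
    evaluate_terms,
    random_cv_probability,
    simulate_chance_validation,
)
from litnav.corpus_model import AuthorName, DocumentRecord
from litnav.search_backend import SearchOutcome


class TestComputeOverlap:
    def test_disjoint_sets(self):
        overlap, self_hit = compute_overlap(["1", "2"], ["3", "4"], "p")
        assert overlap == () and not self_hit

    def test_order_of_results_preserved(self):
        overlap, _ = compute_overlap(["9", "3", "7", "1"], ["1", "3"], "p")
        assert overlap == ("3", "1")

    def test_self_hit_flagged_not_counted(self):
        overlap, self_hit = compute_overlap(["p", "3"], ["3", "p"], "p")
        assert overlap == ("3",) and self_hit

    def test_agr2_expression_overlap_is_six(self, agr2):
        outcome = next(o for o in agr2.outcomes if o.term == "AGR2 expression")
        overlap, self_hit = compute_overlap(
            outcome.result_ids, agr2.paper.cited_ids, agr2.paper.doc_id
        )
        assert len(overlap) == 6 and not self_hit


PAPER_AUTHORS = [AuthorName("Alpha", "A"), AuthorName("Beta", "B")]


class TestClassifyValidation:
    def test_no_overlap_no_self_hit(self):
        assert classify_validation([], False, PAPER_AUTHORS) is Classification.NOT_CV

    def test_disjoint_authors_is_cv_d(self):
        cls = classify_validation(
            ["c1"], False, PAPER_AUTHORS, {"c1": [AuthorName("Gamma", "G")]}
        )
        assert cls is Classification.CV_D

    def test_shared_author_is_cv_s(self):
        cls = classify_validation(
            ["c1"], False, PAPER_AUTHORS, {"c1": [AuthorName("Alpha", "A"), AuthorName("Delta", "D")]}
        )
        assert cls is Classification.CV_S

    def test_self_hit_only_is_cv_s(self):
        assert classify_validation([], True, PAPER_AUTHORS) is Classification.CV_S

    def test_mixed_overlap_takes_cv_d_precedence(self):
        cls = classify_validation(
            ["shared", "disjoint"],
            False,
            PAPER_AUTHORS,
            {"shared": [AuthorName("Alpha", "A")], "disjoint": [AuthorName("Omega", "O")]},
        )
        assert cls is Classification.CV_D

    def test_missing_author_data_conservative(self):
        with pytest.warns(UserWarning):
            cls = classify_validation(["c1"], False, PAPER_AUTHORS, {})
        assert cls is Classification.CV_S

    def test_outcomes_exclusive_exhaustive(self):
        rng = np.random.default_rng(0)
        pool = [AuthorName(f"S{i}", "X") for i in range(6)]
        for _ in range(200):
            overlap = [f"c{i}" for i in range(rng.integers(0, 3))]
            self_hit = bool(rng.integers(0, 2))
            authors = {
                c: [pool[k] for k in rng.integers(0, 6, 2)] for c in overlap
            }
            cls = classify_validation(overlap, self_hit, pool[:2], authors)
            assert cls in Classification
            if not overlap and not self_hit:
                assert cls is Classification.NOT_CV
            else:
                assert cls is not Classification.NOT_CV


class TestEvaluateTerms:
    def test_zero_terms_zero_report(self):
        paper = DocumentRecord(doc_id="p", cited_ids=["1", "2", "3", "4", "5"])
        report = evaluate_terms(paper, [])
        assert report.n_validated_terms == 0
        assert report.unique_validating_citations == 0
        assert report.n_terms_lt5 == 0

    def test_agr2_fixture_counts(self, agr2):
        report = evaluate_terms(agr2.paper, agr2.outcomes, agr2.cited_author_lists)
        assert report.n_cv_d_terms == 15
        assert report.n_cv_s_terms == 1
        assert report.unique_validating_citations == 17
        assert report.unique_cv_d_validators == 16

    def test_validated_terms_partition_into_d_and_s(self, agr2):
        report = evaluate_terms(agr2.paper, agr2.outcomes, agr2.cited_author_lists)
        non_not_cv = sum(
            1 for r in report.records if r.classification is not Classification.NOT_CV
        )
        assert report.n_cv_d_terms + report.n_cv_s_terms == non_not_cv

    def test_nonoverlap_excludes_validators_and_self(self):
        paper = DocumentRecord(
            doc_id="p", cited_ids=["c1", "c2", "c3", "c4", "c5"],
            authors=PAPER_AUTHORS,
        )
        outcome = SearchOutcome(
            term="t", result_ids=("c1", "p", "x1", "x2"), total_hits=4, truncated_at=20
        )
        report = evaluate_terms(paper, [outcome], {"c1": [AuthorName("Zeta", "Z")]})
        rec = report.records[0]
        assert rec.non_overlap_count == 2
        assert rec.self_hit

    def test_report_json_round_trip(self, agr2):
        report = evaluate_terms(agr2.paper, agr2.outcomes, agr2.cited_author_lists)
        back = PaperReport.from_json(json.loads(json.dumps(report.to_json())))
        assert back.to_json() == report.to_json()
        assert back.n_cv_d_terms == report.n_cv_d_terms


class TestEvaluateCandidateList:
    def test_citations_as_candidates_forces_validation(self):
        paper = DocumentRecord(
            doc_id="p", cited_ids=[f"c{i}" for i in range(25)], authors=PAPER_AUTHORS
        )
        report = evaluate_candidate_list(paper, paper.cited_ids[:20])
        assert report.records[0].classification is not Classification.NOT_CV

    def test_agr2_related_citations_four_validators(self, agr2):
        report = evaluate_candidate_list(
            agr2.paper, agr2.related_citations, agr2.cited_author_lists
        )
        assert report.unique_validating_citations == 4
        assert report.records[0].classification is Classification.CV_D

    def test_empty_candidate_list_not_cv(self):
        paper = DocumentRecord(doc_id="p", cited_ids=["c1"])
        report = evaluate_candidate_list(paper, [])
        assert report.records[0].classification is Classification.NOT_CV

    def test_long_list_truncated_with_warning(self):
        paper = DocumentRecord(doc_id="p", cited_ids=["c99"])
        with pytest.warns(UserWarning):
            report = evaluate_candidate_list(paper, [f"x{i}" for i in range(30)])
        assert len(report.records[0].result_ids) == 20


def _report(paper_id, cv_d, cv_s=0, lt5=0):
    records = []
    for i in range(cv_d):
        records.append(
            ValidationRecord(
                term=f"d{i}", result_ids=("r",), overlapping_ids=("r",), self_hit=False,
                classification=Classification.CV_D,
                non_overlap_count=0 if i < lt5 else 30, total_hits=1 if i < lt5 else 31,
            )
        )
    for i in range(cv_s):
        records.append(
            ValidationRecord(
                term=f"s{i}", result_ids=(), overlapping_ids=(), self_hit=True,
                classification=Classification.CV_S, non_overlap_count=10, total_hits=10,
            )
        )
    return PaperReport(paper_id=paper_id, records=records)


class TestAggregate:
    def test_all_cv_d_degenerate_ci(self):
        summary = aggregate([_report("a", 1), _report("b", 2)])
        assert summary.pct_papers_cv_d == 100.0
        assert summary.ci_cv_d == (100.0, 100.0)

    def test_half_cv_d(self):
        summary = aggregate([_report("a", 1), _report("b", 0)])
        assert summary.pct_papers_cv_d == 50.0

    def test_large_sample_ci_matches_normal_approximation(self):
        # 759 of 883 flagged: p = 85.96%, Wald interval [83.66, 88.25] pre-rounding
        reports = [_report(str(i), 1 if i < 759 else 0) for i in range(883)]
        summary = aggregate(reports)
        assert summary.pct_papers_cv_d == pytest.approx(85.957, abs=0.01)
        assert summary.ci_cv_d == (83.0, 89.0)  # rounded outward to whole percents
        assert summary.ci_cv_d[0] <= summary.pct_papers_cv_d <= summary.ci_cv_d[1]

    def test_sample_sd_used(self):
        summary = aggregate([_report("a", 2), _report("b", 4)])
        assert summary.mean_cv_d_terms == 3.0
        assert summary.sd_cv_d_terms == pytest.approx(np.std([2, 4], ddof=1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])

    def test_bucket_percentages(self):
        summary = aggregate([_report("a", 2, lt5=1), _report("b", 1, lt5=0)])
        assert summary.pct_with_term_lt5 == 50.0
        assert summary.pct_with_term_gt20 == 100.0


class TestNullModel:
    def test_no_citations_zero_probability(self):
        assert random_cv_probability(0, 100) == 0.0

    def test_certainty_when_everything_cited(self):
        assert random_cv_probability(100, 100, k=1) == 1.0

    def test_pubmed_scale_value(self):
        p = random_cv_probability(100, 18_000_000, 20)
        assert p == pytest.approx(1.11108e-4, rel=1e-4)
        assert p < 0.0002  # below the 0.02% bound

    def test_monotone_in_c_and_k(self):
        base = random_cv_probability(50, 10_000, 20)
        assert random_cv_probability(60, 10_000, 20) >= base
        assert random_cv_probability(50, 10_000, 25) >= base

    def test_linear_approximation_error_bound(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(1000, 10**6))
            c = int(rng.integers(0, n // 100))
            k = int(rng.integers(1, 40))
            a = k * c / n
            if a >= 0.5:
                continue
            p = random_cv_probability(c, n, k)
            assert 0.0 <= p <= 1.0
            assert abs(p - a) <= a**2

    def test_params_object(self):
        params = NullModelParams(c=100, n=18_000_000)
        assert params.probability == random_cv_probability(100, 18_000_000, 20)
        assert params.linear_approximation == pytest.approx(2000 / 18_000_000)
        with pytest.raises(ValueError):
            NullModelParams(c=10, n=5)

    def test_small_simulation_matches_analytic(self):
        # quick calibration check; the full-size run lives in the acceptance suite
        n, c, k, searches = 500, 10, 20, 4000
        rate = simulate_chance_validation(n, c, k, searches, seed=11)
        p = random_cv_probability(c, n, k)
        se = np.sqrt(p * (1 - p) / searches)
        assert abs(rate - p) <= 3 * se + 0.01
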