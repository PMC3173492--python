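import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from litnav.phrase_extraction import CandidatePhrase, PhraseStats
from litnav.phrase_ranking import (
    Bin,
    DegenerateDesignError,
    LogPoint,
    RankingMethod,
    assign_bin,
    constant_quantile_fit,
    fit_quantile_line,
    pinball_loss,
    rank_phrases,
    residual_score,
    select_terms,
    tfidf_score,
)


def points(xy):
    return [LogPoint(x=float(x), y=float(y)) for x, y in xy]


def vertex_oracle(x, y, tau):
    """Exact brute-force pinball optimum: some optimal line interpolates two points."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    best = math.inf
    n = len(x)
    for i in range(n):
        best = min(best, pinball_loss(y - y[i], tau))  # horizontal candidates
        for j in range(i + 1, n):
            if x[i] == x[j]:
                continue
            m = (y[j] - y[i]) / (x[j] - x[i])
            c = y[i] - m * x[i]
            best = min(best, pinball_loss(y - m * x - c, tau))
    return best


class TestFitQuantileLine:
    @pytest.mark.parametrize("tau", [0.25, 0.5, 0.9])
    def test_collinear_points_recovered_exactly(self, tau):
        fit = fit_quantile_line(points([(0, 1), (1, 3), (2, 5)]), tau)
        assert fit.m == pytest.approx(2.0, abs=1e-8)
        assert fit.c == pytest.approx(1.0, abs=1e-8)
        assert fit.loss == pytest.approx(0.0, abs=1e-9)

    def test_grid_search_example(self):
        """Loss matches an exhaustive (coarse-then-refined) grid over (m, c)."""
        pts = points([(0, 0), (1, 1), (2, 2), (1, 5)])
        x = np.array([p.x for p in pts])
        y = np.array([p.y for p in pts])
        coarse = np.arange(-10, 10.05, 0.05)
        best, best_mc = math.inf, (0.0, 0.0)
        for m in coarse:
            losses = [pinball_loss(y - m * x - c, 0.5) for c in coarse]
            k = int(np.argmin(losses))
            if losses[k] < best:
                best, best_mc = losses[k], (m, coarse[k])
        fine_m = np.arange(best_mc[0] - 0.06, best_mc[0] + 0.06, 1e-3)
        fine_c = np.arange(best_mc[1] - 0.06, best_mc[1] + 0.06, 1e-3)
        grid_best = min(
            pinball_loss(y - m * x - c, 0.5) for m in fine_m for c in fine_c
        )
        fit = fit_quantile_line(pts, 0.5)
        assert fit.loss <= grid_best + 1e-6

    def test_median_fit_recovers_line_under_symmetric_noise(self):
        eps = 0.01
        xs = np.arange(10, dtype=float)
        pts = [
            LogPoint(x=x, y=2 * x + 1 + (eps if i % 2 else -eps))
            for i, x in enumerate(xs)
        ]
        fit = fit_quantile_line(pts, 0.5)
        assert fit.m == pytest.approx(2.0, abs=2 * eps)
        assert fit.c == pytest.approx(1.0, abs=2 * eps)

    def test_degenerate_design_raises(self):
        with pytest.raises(DegenerateDesignError):
            fit_quantile_line(points([(1, 0), (1, 5), (1, 9)]), 0.5)

    def test_constant_fallback_is_quantile(self):
        fit = constant_quantile_fit(points([(1, 0), (1, 5), (1, 9)]), 0.5)
        assert fit.m == 0.0 and fit.c == 5.0

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            fit_quantile_line(points([(0, 0), (1, 1)]), 1.0)

    @pytest.mark.parametrize("tau", [0.3, 0.5, 0.8])
    def test_matches_vertex_oracle_on_random_instances(self, tau):
        rng = np.random.default_rng(20)
        for _ in range(40):
            n = int(rng.integers(2, 9))
            x = rng.integers(0, 5, n).astype(float)
            if np.ptp(x) == 0:
                x[0] += 1.0
            y = rng.normal(size=n).round(2)
            fit = fit_quantile_line(points(zip(x, y)), tau)
            assert fit.loss <= vertex_oracle(x, y, tau) + 1e-6

    def test_agrees_with_statsmodels_quantreg(self):
        """Independent cross-check: the LP fit attains a loss no worse than
        statsmodels' IRLS quantile regression on the same data."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        x = rng.uniform(0, 5, 40)
        y = 1.5 * x + rng.standard_t(3, size=40)
        for tau in (0.25, 0.5, 0.75):
            fit = fit_quantile_line(points(zip(x, y)), tau)
            model = sm.QuantReg(y, sm.add_constant(x)).fit(q=tau)
            sm_loss = pinball_loss(y - model.params[1] * x - model.params[0], tau)
            assert fit.loss <= sm_loss + 1e-6
            assert fit.m == pytest.approx(model.params[1], abs=0.05)

    def test_quantile_property(self):
        rng = np.random.default_rng(3)
        for tau in (0.25, 0.5, 0.75):
            x = rng.normal(size=60)
            y = rng.normal(size=60)
            fit = fit_quantile_line(points(zip(x, y)), tau)
            resid = y - fit.m * x - fit.c
            n = len(x)
            assert np.mean(resid > 1e-9) <= 1 - tau + 2 / n
            assert np.mean(resid < -1e-9) <= tau + 2 / n


class TestScores:
    def test_residual_examples(self):
        from litnav.phrase_ranking import LineFit

        fit = LineFit(m=1.0, c=0.0, tau=0.5, loss=0.0)
        assert residual_score(fit, LogPoint(x=2, y=3)) == pytest.approx(1.0)
        assert residual_score(fit, LogPoint(x=2, y=2)) == 0.0
        delta = 0.37
        assert residual_score(fit, LogPoint(x=2, y=3 + delta)) == pytest.approx(1.0 + delta)

    def test_tfidf_examples(self):
        assert tfidf_score(1, 0) == pytest.approx(1.0)  # log10(10) = 1
        assert tfidf_score(10, 50) == pytest.approx(2 * tfidf_score(5, 50))
        assert tfidf_score(5, 100) > tfidf_score(5, 10**6)


class TestAssignBin:
    @pytest.mark.parametrize(
        "bg,expected",
        [
            (20_000_000, Bin.BROAD),
            (10_000_001, Bin.BROAD),
            (10_000_000, Bin.SPECIFIC),
            (100, Bin.SPECIFIC),
            (99, Bin.RARE),
            (0, Bin.RARE),
        ],
    )
    def test_boundaries(self, bg, expected):
        assert assign_bin(bg) is expected

    def test_partition_of_counts(self):
        rng = np.random.default_rng(1)
        for bg in np.concatenate([rng.integers(0, 2 * 10**7, 500), [0, 99, 100, 10**7, 10**7 + 1]]):
            assert assign_bin(int(bg)) in Bin  # exactly one bin, total function


def _stats(triples):
    """[(text, doc_count, bg_count)] -> PhraseStats list."""
    return [
        PhraseStats(
            phrase=CandidatePhrase(tokens=tuple(text.split()), pattern="N" * len(text.split())),
            doc_count=dc,
            bg_count=bg,
        )
        for text, dc, bg in triples
    ]


def _zipf_background(n=200, seed=0):
    rng = np.random.default_rng(seed)
    return [
        (f"w{i}", 1, int(1e6 / (i + 1) ** 1.2) + int(rng.integers(0, 3)))
        for i in range(n)
    ]


class TestRankPhrases:
    def test_single_phrase_gets_rank_one(self):
        ranked = rank_phrases(_stats([("solo", 3, 50)]))
        assert len(ranked) == 1 and ranked[0].rank == 1

    def test_planted_outlier_ranks_first(self):
        stats = _stats([("planted outlier", 20, 3)] + _zipf_background())
        ranked = rank_phrases(stats, method=RankingMethod.RESIDUAL)
        assert ranked[0].phrase.text == "planted outlier"

    def test_residual_and_tfidf_orderings_correlate(self):
        rng = np.random.default_rng(11)
        triples = [
            (f"p{i}", int(rng.integers(1, 30)), int(rng.integers(0, 10**6)))
            for i in range(100)
        ]
        ranked = rank_phrases(_stats(triples))
        rho = spearmanr(
            [rp.residual for rp in ranked], [rp.tfidf for rp in ranked]
        ).statistic
        assert rho > 0

    def test_ranking_invariant_to_input_order(self):
        stats = _stats(_zipf_background(50, seed=5))
        forward = [rp.phrase.text for rp in rank_phrases(stats)]
        backward = [rp.phrase.text for rp in rank_phrases(list(reversed(stats)))]
        assert forward == backward

    def test_ranks_contiguous_from_one(self):
        ranked = rank_phrases(_stats(_zipf_background(30)))
        assert [rp.rank for rp in ranked] == list(range(1, 31))

    def test_degenerate_background_still_ranks(self):
        # all phrases share one bg count -> constant-fit fallback
        ranked = rank_phrases(_stats([("a", 5, 10), ("b", 1, 10), ("c", 2, 10)]))
        assert [rp.phrase.text for rp in ranked] == ["a", "c", "b"]


class TestSelectTerms:
    def test_exhaustion_below_cap(self):
        stats = _stats([(f"s{i}", 1, 500) for i in range(5)] + [(f"r{i}", 1, 3) for i in range(3)])
        terms = select_terms(rank_phrases(stats), per_bin=20)
        assert len(terms) == 8

    def test_forty_term_maximum(self):
        stats = _stats(
            [(f"s{i}", 1, 500) for i in range(100)] + [(f"r{i}", 1, 3) for i in range(100)]
        )
        terms = select_terms(rank_phrases(stats), per_bin=20)
        assert len(terms) == 40
        assert sum(1 for t in terms if t.bin is Bin.SPECIFIC) == 20
        assert sum(1 for t in terms if t.bin is Bin.RARE) == 20

    def test_broad_only_ranking_selects_nothing(self):
        stats = _stats([(f"b{i}", 1, 2 * 10**7) for i in range(10)])
        assert select_terms(rank_phrases(stats)) == []

    def test_selection_preserves_score_order(self):
        stats = _stats(_zipf_background(80, seed=2))
        terms = select_terms(rank_phrases(stats), per_bin=10)
        for bin_ in (Bin.SPECIFIC, Bin.RARE):
            ranks = [t.rank for t in terms if t.bin is bin_]
            assert ranks == sorted(ranks)

    def test_single_adjectives_excludable(self):
        adj = PhraseStats(phrase=CandidatePhrase(tokens=("blue",), pattern="A"), doc_count=9, bg_count=3)
        stats = _stats([("r0", 1, 3)]) + [adj]
        with_adj = select_terms(rank_phrases(stats))
        without = select_terms(rank_phrases(stats), include_single_adjectives=False)
        assert any(t.phrase.pattern == "A" for t in with_adj)
        assert not any(t.phrase.pattern == "A" for t in without)
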