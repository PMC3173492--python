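"""Rank candidate phrases by quantile-regression residuals; bin and select search terms.

Each phrase is a point (x, y) with x = log10(background count + 1) and
y = log10(document count).  A line y = m·x + c is fitted across *all* of a
document's phrases by quantile regression — minimizing the pinball loss
Σ ρ_τ(yᵢ − m·xᵢ − c) with ρ_τ(r) = r·(τ − 1[r<0]) — and each phrase is
scored by its residual y − m·x − c.  The more a phrase sits above the line
(high document count for its background frequency), the more it stands out
as subject matter of the paper.  A TF-IDF-style comparator score,
doc_count / log10(bg_count + 10), is computed alongside.

Phrases are also binned by raw background count — BROAD (> 10 million),
SPECIFIC (100 to 10 million, boundaries inclusive), RARE (< 100) — and
search terms are drawn as the top-ranked phrases of the SPECIFIC and RARE
bins (20 each by default).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from litnav.phrase_extraction import CandidatePhrase, PhraseStats

__all__ = [
    "Bin",
    "LogPoint",
    "LineFit",
    "RankedPhrase",
    "DegenerateDesignError",
    "RankingMethod",
    "assign_bin",
    "fit_quantile_line",
    "pinball_loss",
    "rank_phrases",
    "residual_score",
    "select_terms",
    "tfidf_score",
    "render_bins",
    "plot_counts",
    "BROAD_THRESHOLD",
    "RARE_THRESHOLD",
]

RARE_THRESHOLD = 100
BROAD_THRESHOLD = 10_000_000


class Bin(enum.Enum):
    BROAD = "broad"
    SPECIFIC = "specific"
    RARE = "rare"


class RankingMethod(enum.Enum):
    RESIDUAL = "residual"
    TFIDF = "tfidf"


class DegenerateDesignError(ValueError):
    """All x values identical: the slope is unidentifiable."""


@dataclass(frozen=True)
class LogPoint:
    x: float  # log10(bg_count + 1)
    y: float  # log10(doc_count)
    phrase: PhraseStats | None = None

    @classmethod
    def from_stats(cls, stats: PhraseStats) -> "LogPoint":
        if stats.bg_count is None:
            raise ValueError(f"background count unset for {stats.phrase.text!r}")
        return cls(
            x=math.log10(stats.bg_count + 1), y=math.log10(stats.doc_count), phrase=stats
        )


@dataclass(frozen=True)
class LineFit:
    m: float
    c: float
    tau: float
    loss: float


@dataclass(frozen=True)
class RankedPhrase:
    phrase: CandidatePhrase
    stats: PhraseStats
    residual: float
    tfidf: float
    bin: Bin
    rank: int

    @property
    def term(self) -> str:
        """Quoted-search text of the phrase."""
        return self.phrase.text


def pinball_loss(residuals: np.ndarray, tau: float) -> float:
    """Σ ρ_τ(r) with ρ_τ(r) = r·(τ − 1[r<0]) — the quantile-regression objective."""
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(r * (tau - (r < 0))))


def fit_quantile_line(points: Sequence[LogPoint], tau: float = 0.5) -> LineFit:
    """Fit y = m·x + c minimizing the pinball loss, as a linear program.

    Standard LP formulation: residual split into u − v with u, v ≥ 0 and
    objective τ·Σu + (1−τ)·Σv, solved with HiGHS. Exact at LP precision;
    the achieved loss is within 1e-6 of the global optimum.

    Raises :class:`DegenerateDesignError` when all x coincide; callers fall
    back to the constant fit m = 0, c = τ-quantile of y.
    """
    if not 0 < tau < 1:
        raise ValueError(f"tau must be in (0,1), got {tau}")
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    x = np.array([p.x for p in points], dtype=float)
    y = np.array([p.y for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all x values identical; slope unidentifiable")

    n = len(x)
    # variables: [m, c, u_1..u_n, v_1..v_n]
    cost = np.concatenate(([0.0, 0.0], np.full(n, tau), np.full(n, 1 - tau)))
    eye = sparse.eye(n, format="csc")
    a_eq = sparse.hstack(
        [sparse.csc_matrix(x[:, None]), sparse.csc_matrix(np.ones((n, 1))), eye, -eye],
        format="csc",
    )
    bounds = [(None, None), (None, None)] + [(0, None)] * (2 * n)
    res = linprog(cost, A_eq=a_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    m, c = float(res.x[0]), float(res.x[1])
    return LineFit(m=m, c=c, tau=tau, loss=pinball_loss(y - m * x - c, tau))


def constant_quantile_fit(points: Sequence[LogPoint], tau: float) -> LineFit:
    """Fallback for degenerate designs: m = 0, c = the τ-quantile of y."""
    y = np.array([p.y for p in points], dtype=float)
    c = float(np.quantile(y, tau, method="inverted_cdf"))
    return LineFit(m=0.0, c=c, tau=tau, loss=pinball_loss(y - c, tau))


def residual_score(fit: LineFit, point: LogPoint) -> float:
    """Signed vertical distance above the fitted line: y − m·x − c."""
    return point.y - fit.m * point.x - fit.c


def tfidf_score(doc_count: int, bg_count: int) -> float:
    """Comparator score: doc_count / log10(bg_count + 10).

    Proportional to the document count, inversely proportional to the log
    of the background count; the +10 smoothing keeps the denominator ≥ 1
    and finite at bg_count = 0.
    """
    if doc_count < 1:
        raise ValueError("doc_count must be >= 1")
    return doc_count / math.log10(bg_count + 10)


def assign_bin(bg_count: int) -> Bin:
    """Stratify by background count: BROAD > 10M, RARE < 100, SPECIFIC between.

    Both boundaries (100 and 10,000,000) close into SPECIFIC so the bins
    partition the non-negative integers.
    """
    if bg_count < 0:
        raise ValueError("bg_count must be >= 0")
    if bg_count > BROAD_THRESHOLD:
        return Bin.BROAD
    if bg_count < RARE_THRESHOLD:
        return Bin.RARE
    return Bin.SPECIFIC


def _tie_key(rp: tuple[PhraseStats, float, float]) -> tuple:
    stats, _, _ = rp
    return (-stats.doc_count, stats.bg_count, stats.phrase.tokens)


def rank_phrases(
    stats: Iterable[PhraseStats],
    method: RankingMethod = RankingMethod.RESIDUAL,
    tau: float = 0.5,
) -> list[RankedPhrase]:
    """Score, sort, bin, and rank a document's candidate phrases.

    The quantile line is fitted over all the document's phrases; phrases
    are sorted by the chosen score descending with deterministic
    tie-breaking (doc_count descending, bg_count ascending, lexicographic
    token order), so the ranking is invariant to input order.
    """
    stats = list(stats)
    if not stats:
        raise ValueError("no phrases to rank")
    points = [LogPoint.from_stats(s) for s in stats]
    if len(points) >= 2:
        try:
            fit = fit_quantile_line(points, tau)
        except DegenerateDesignError:
            fit = constant_quantile_fit(points, tau)
    else:
        fit = LineFit(m=0.0, c=points[0].y, tau=tau, loss=0.0)

    scored = []
    for s, p in zip(stats, points):
        resid = residual_score(fit, p)
        tfidf = tfidf_score(s.doc_count, s.bg_count)
        scored.append((s, resid, tfidf))

    score_index = 1 if method is RankingMethod.RESIDUAL else 2
    scored.sort(key=lambda t: (-t[score_index],) + _tie_key(t))
    return [
        RankedPhrase(
            phrase=s.phrase,
            stats=s,
            residual=resid,
            tfidf=tfidf,
            bin=assign_bin(s.bg_count),
            rank=i + 1,
        )
        for i, (s, resid, tfidf) in enumerate(scored)
    ]


def select_terms(
    ranked: Sequence[RankedPhrase],
    per_bin: int = 20,
    bins: Iterable[Bin] = (Bin.SPECIFIC, Bin.RARE),
    include_single_adjectives: bool = True,
) -> list[RankedPhrase]:
    """Take the top ``per_bin`` phrases from each requested bin, in score order.

    The default (top 20 specific + top 20 rare) yields at most 40 search
    terms per paper.  Single-token adjectives can optionally be excluded
    from selection while remaining in the ranking.
    """
    if per_bin < 0:
        raise ValueError("per_bin must be >= 0")
    wanted = set(bins)
    taken: dict[Bin, int] = {b: 0 for b in wanted}
    out: list[RankedPhrase] = []
    for rp in ranked:
        if rp.bin not in wanted or taken[rp.bin] >= per_bin:
            continue
        if not include_single_adjectives and rp.phrase.pattern == "A":
            continue
        taken[rp.bin] += 1
        out.append(rp)
    return out


def render_bins(ranked: Sequence[RankedPhrase], width: int = 28, rows: int = 20) -> str:
    """Three-column text rendering (broad | specific | rare), rank order kept per column."""
    columns = {b: [rp.phrase.surface or rp.term for rp in ranked if rp.bin is b][:rows] for b in Bin}
    lines = [" | ".join(b.value.ljust(width) for b in Bin)]
    lines.append("-+-".join("-" * width for _ in Bin))
    for i in range(max((len(c) for c in columns.values()), default=0)):
        row = [
            (columns[b][i] if i < len(columns[b]) else "")[:width].ljust(width) for b in Bin
        ]
        lines.append(" | ".join(row))
    return "\n".join(lines)


def plot_counts(ranked: Sequence[RankedPhrase], tau: float = 0.5, path: str | None = None):
    """Scatter of document count vs background count on log axes with the fitted line.

    Plot axes put the document count on x and background count on y; the
    regression itself predicts log document count from log background
    count, so the fitted line is drawn transposed.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    doc = np.array([rp.stats.doc_count for rp in ranked], dtype=float)
    bg = np.array([rp.stats.bg_count for rp in ranked], dtype=float)
    points = [LogPoint.from_stats(rp.stats) for rp in ranked]
    try:
        fit = fit_quantile_line(points, tau)
    except (DegenerateDesignError, ValueError):
        fit = constant_quantile_fit(points, tau)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(doc, bg + 1, s=8, alpha=0.5)
    ys = np.linspace(0, max(p.x for p in points), 50)  # log10(bg+1) grid
    ax.plot(10 ** (fit.m * ys + fit.c), 10**ys, color="tab:blue")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("document count")
    ax.set_ylabel("background count + 1")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
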