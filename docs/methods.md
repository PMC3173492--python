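# Methods

## Phrase extraction

Text is taken from a record's title, abstract, and body prose; reference
lists are excluded at read time because reference strings would inflate
phrase counts with the titles of cited papers. Sentences are split at
`. ! ?` boundaries followed by an upper-case or numeric opener, with an
abbreviation list (Dr., Fig., et al., …) and single-initial protection.
Word tokenization keeps hyphenated tokens intact ("XAG-2", "hAG-2",
"up-regulated" are single tokens), since gene symbols and similar
terminology are exactly the phrases worth searching.

Part-of-speech tagging is consumed through a minimal contract — any callable
mapping a token list to an equal-length list of Penn-style fine tags — plus
a shipped tag map that collapses all noun tags (including proper nouns) to
NOUN, all adjective tags to ADJ, and everything else to OTHER. The default
implementation is a rule-based tagger (closed-class lexicon, suffix
heuristics, noun default for unknown content words). Taggers of this family
run at roughly 90–97 % token accuracy; mis-taggings are deliberately left
uncorrected and flow through to the extracted phrases, exactly as they would
with any statistical tagger. A sentence on which a tagger raises is skipped
with a warning rather than failing the document.

Chunking emits every single NOUN, every single ADJ, and — within each
maximal run of adjective/noun tokens — every contiguous sub-span of length
2..`max_phrase_len` that ends in a noun (patterns AN, NN, ANN, …).
`max_phrase_len` defaults to 5; useful query phrases in practice run up to
about four tokens. Counting is per emission over all sentences, so a
sub-span's document count is always at least that of any span containing it.
Phrase identity is the case-folded token sequence; the first-seen
original-cased surface form is retained for display and quoted search. An
open choice worth noting: occurrences are counted per sub-span rather than
per maximal chunk only — with sub-span counting, "cement gland" counts every
time it appears, also inside "cement gland gene".

## Ranking

Each phrase becomes a point `(x, y)` with `x = log10(bg_count + 1)` (the +1
admits zero background counts) and `y = log10(doc_count)`. The quantile line
is fitted over **all** of the document's phrases by minimizing the pinball
loss; the fit is posed as the standard linear program (residuals split into
nonnegative parts, objective `τ·Σu + (1−τ)·Σv`) and solved with HiGHS, which
is exact to LP tolerance. τ defaults to 0.5 (median regression, the
canonical choice when no level is otherwise dictated) and is exposed in the
configuration. If all phrases share one background count the design is
degenerate and the fit falls back to the constant τ-quantile of `y`.

Phrases are ordered by residual `y − m·x − c` descending. Tie-breaking is
deterministic: higher document count first, then lower background count,
then lexicographic token order — so the ranking is invariant to input order.
The TF-IDF comparator is `doc_count / log10(bg_count + 10)`; only
proportionality matters for its use as a comparator, and the +10 smoothing
keeps the denominator ≥ 1 and finite at `bg_count = 0`. On generated
documents the two orderings correlate positively (Spearman), which is the
operational sense in which the residual ranking is "comparable to TF-IDF".

Bins: BROAD for background counts above 10 million, RARE below 100,
SPECIFIC between, with **both** boundaries (100 and 10 000 000) closed into
SPECIFIC so the three bins partition the non-negative integers. Search-term
selection takes the top 20 of SPECIFIC and RARE each (≤ 40 terms); single
adjectives can be excluded from selection by configuration while remaining
in the ranking.

For plotting, the count–count scatter puts the document count on the x-axis
and background count on the y-axis while the regression itself predicts log
document count from log background count; the fitted line is drawn
transposed onto the plot axes.

## Search

The local backend indexes title + abstract only, matching the scope of
remote title/abstract queries. A quoted term matches a document when its
word-token sequence occurs contiguously within one field, case-insensitively
— never across the title/abstract boundary; punctuation tokens are ignored
on both sides. Results are ordered by publication date descending (document
id descending on ties), reproducing the recency ordering of real literature
search engines, and truncated to the top 20 by default; the untruncated hit
count is kept because the </20/>20 report buckets cannot be derived from a
truncated list. The remote adapter speaks an esearch-style API over stdlib
HTTP with bounded retries and a JSON response cache keyed by (term, date) so
recorded sessions replay without network; it is never exercised by the test
suite.

## Citation validation

Overlap is the intersection of a candidate list with the paper's cited ids,
preserving result order; the paper's own id in the results is flagged as a
self-hit and never counted in the overlap. Classification: NOT_CV with no
overlap and no self-hit; CV_D if **any** overlapping citation's author set
is disjoint from the paper's; otherwise CV_S (shared-author validators or a
self-hit only). CV_D precedence makes D and S a partition of validated
terms. Author identity is the case-folded, diacritic-stripped surname plus
first initial — the richest key citation tables reliably carry. An
overlapping citation with no author data is conservatively treated as
shared-author (with a warning), biasing against CV_D claims.

Per-paper reports count CV-D/CV-S terms, distinct validating citations
(pooled across D and S, self-hits included as one distinct validator; a
separate field counts CV-D validators only), and how many validated terms
have < 5, < 20, or > 20 non-overlapping results, where the non-overlap count
is total hits minus validating citations and self-hits. Corpus summaries
report percentages with 95 % Wald intervals `p ± 1.96·√(p(1−p)/n)` rounded
outward to whole percents (Wilson or exact intervals could be substituted;
the aggregation is a pure function of the per-paper reports, so summaries
are bit-reproducible from report files). Count metrics use means and sample
standard deviations.

The chance model `1 − (1 − C/N)^k` treats a k-result list as k independent
uniform draws; the Monte-Carlo calibration draws both citation lists and
result lists uniformly *without* replacement, whose exact law is
hypergeometric — at the calibration's size (N = 2000, C = k = 20) the two
differ by ≈ 1 × 10⁻⁴, far below Monte-Carlo noise at 10 000 searches.

## Synthetic corpus

The generator emulates the structure the method exploits, at desk scale:

- **Background counts** are a deterministic Zipf law over the pooled
  vocabulary (`count(rank) ∝ rank^−s`, s = 1.1, top rank ≈ 5 × 10⁷ so the
  head lands in BROAD and the tail in SPECIFIC). Signature phrases get
  counts drawn below 100 (RARE).
- **Papers** belong to topics (60 papers, 6 topics by default) and each
  carries a two-token rare *signature phrase* in its own title, abstract,
  and body. Citations (5–10 per paper) stay within topic with probability
  0.9. With probability `phrase_share_prob` (default 1) a citing paper's
  body also contains each cited paper's signature, repeated 3–6 times — the
  mechanism that makes cited papers *findable* from the citing paper's text.
- **Selectivity**: body filler is drawn from a 400-word Zipf vocabulary
  *without replacement* (so filler stays at document count 1 and planted
  signatures are the only repeated rare phrases), while title/abstract
  filler comes from a separate 3000-word vocabulary so any single word
  occurs in only a handful of titles. This reproduces, at N = 60, the
  selectivity quoted searches have at web scale; without it, a tiny corpus
  makes every 20-hit search chance-validated and the benchmark saturates.
- **Authors** are unique per paper, so cross-paper validations are CV-D by
  construction and self-hits are the only CV-S source.
- Documents are plain text, but built entirely from vocabulary whose tag is
  fixed by construction; the bundle ships a lexicon tagger over that
  vocabulary, so pipeline tests isolate chunking and ranking from tagging
  heuristics. All randomness flows from the single generator seed.

What the generator does **not** emulate: real linguistic structure (function
words, verbs, morphology), realistic publication-date distributions (dates
are uniform), author overlap between papers (no CV-S-via-coauthor cases),
citation of documents outside the corpus, and the many-orders-of-magnitude
corpus scale of real literature. Passing end-to-end tests therefore shows
the machinery is correct and the signal→validation mechanism works where it
exists; it does not estimate real-world CV rates, which were measured
against a live corpus and are not reproducible at desk scale.

`shuffle_citations` replaces every citation list with a uniform random
sample of equal size, leaving all text unchanged — the null construction
behind the chance-validation argument. On default conditions the true graph
yields CV-D terms for ~100 % of papers versus ~75 % under shuffling (the
shuffled rate is far above the web-scale null because N = 60 makes the
per-search chance `C/(N−1)` ≈ 0.1; the separation, not the absolute level,
is the tested property).

## Numerical and design notes

- Quantile LP: exact at solver tolerance; tests compare against an
  independent brute-force oracle that enumerates all two-point lines plus
  horizontal lines through each point (every LP vertex), which is exact for
  the small instances used.
- Problem sizes: oracle sweeps use 200 random fit instances (n ≤ 8) and
  1000 random tag sequences; the pipeline benchmark uses 100 corpora of 60
  papers in the test suite and 20 in the acceptance script; the Monte-Carlo
  calibration uses 10 000 simulated searches.
- Degenerate inputs: empty documents yield zero-term reports; punctuation-
  only search terms are rejected; duplicate citation rows collapse with a
  warning; a corpus with duplicate ids is invalid.
- The 1000→883 sample-filter example in the tests mirrors the benchmark's
  ≥ 5-citation filter on a constructed 1000-paper corpus.
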