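"""Part-of-speech tagging contract and a rule-based default tagger.

Downstream code consumes a *tagger contract*: any callable mapping a list of
word tokens to an equal-length list of fine-grained (Penn-style) tags.  A
tag map then reduces fine tags to the coarse set {NOUN, ADJ, OTHER}, which
is all the phrase chunker needs.

The default :class:`RuleBasedTagger` combines a closed-class lexicon with
suffix heuristics and defaults unknown content words to nouns.  Taggers of
this family run at roughly 90-97% token accuracy depending on corpus;
mis-taggings are tolerated and flow through to the extracted phrases rather
than being corrected post hoc.
"""

from __future__ import annotations

import re
from typing import Callable, Sequence

__all__ = ["Tagger", "PENN_TAG_MAP", "RuleBasedTagger", "coarse_tag", "default_tagger"]

# contract: list of tokens -> list of fine tags, same length
Tagger = Callable[[Sequence[str]], list[str]]

#: Penn-Treebank-style fine tag -> coarse {NOUN, ADJ, OTHER} reduction.
#: All noun tags (incl. proper nouns) collapse to NOUN, all adjective tags
#: to ADJ; the chunker only ever uses these two classes.
PENN_TAG_MAP: dict[str, str] = {
    "NN": "NOUN",
    "NNS": "NOUN",
    "NNP": "NOUN",
    "NNPS": "NOUN",
    "JJ": "ADJ",
    "JJR": "ADJ",
    "JJS": "ADJ",
}


def coarse_tag(fine: str) -> str:
    return PENN_TAG_MAP.get(fine, "OTHER")


_DETERMINERS = {"the", "a", "an", "this", "that", "these", "those", "each", "every", "no", "any", "some", "all", "both"}
_PREPOSITIONS = {
    "of", "in", "on", "at", "by", "for", "with", "from", "to", "into", "through", "during",
    "between", "among", "over", "under", "above", "below", "across", "against", "about",
    "toward", "towards", "upon", "within", "without", "per", "via", "versus", "than", "as",
    "including", "compared",
}
_CONJUNCTIONS = {"and", "or", "but", "nor", "so", "yet", "if", "because", "although", "while", "whereas"}
_PRONOUNS = {
    "i", "you", "he", "she", "it", "we", "they", "me", "him", "her", "us", "them",
    "his", "its", "their", "our", "your", "my", "who", "whom", "whose", "which", "what",
}
_VERBS = {
    "is", "are", "was", "were", "be", "been", "being", "am",
    "has", "have", "had", "having", "do", "does", "did", "done",
    "can", "could", "will", "would", "shall", "should", "may", "might", "must",
    "show", "shows", "shown", "showed", "find", "finds", "found",
    "use", "uses", "used", "make", "makes", "made", "ran", "run", "runs", "won", "win",
    "suggest", "suggests", "suggested", "indicate", "indicates", "indicated",
    "observe", "observes", "observed", "report", "reports", "reported",
}
_ADVERBS = {"not", "very", "also", "however", "often", "then", "there", "here", "when", "where", "well", "more", "most", "up", "down", "out"}

#: common adjectives that suffix rules alone would miss
_ADJECTIVE_LEXICON = {
    "blue", "red", "green", "black", "white", "new", "old", "young", "big", "small",
    "high", "low", "higher", "lower", "highest", "lowest", "large", "larger", "largest",
    "human", "murine", "multiple", "several", "other", "same", "different", "such",
    "non-malignant", "malignant", "benign", "normal", "recent", "early", "late",
    "broad", "rare", "common", "good", "best", "better", "first", "second", "third",
}

_ADJ_SUFFIXES = ("ous", "ful", "ive", "able", "ible", "ic", "ical", "ant", "ary", "less", "ish", "like", "ar")
_WORD_RE = re.compile(r"[A-Za-z]")
_NUM_RE = re.compile(r"^[0-9]+([.,][0-9]+)*$")


class RuleBasedTagger:
    """Lexicon + suffix tagger over a Penn-style tagset.

    Resolution order: punctuation/number tags, closed-class lexicon,
    adjective lexicon, verb-form suffixes (-ing, -ed), adjective suffixes,
    -ly adverbs, then a noun default (proper noun when capitalized
    mid-text or containing digits).  Extend via the ``lexicon`` argument,
    a ``token.casefold() -> fine tag`` mapping consulted first.
    """

    def __init__(self, lexicon: dict[str, str] | None = None) -> None:
        self.lexicon = dict(lexicon or {})

    def _tag_one(self, token: str) -> str:
        low = token.casefold()
        if low in self.lexicon:
            return self.lexicon[low]
        if not _WORD_RE.search(token):
            return "CD" if _NUM_RE.match(token) else "."
        if low in _DETERMINERS:
            return "DT"
        if low == "to":
            return "TO"
        if low in _PREPOSITIONS:
            return "IN"
        if low in _CONJUNCTIONS:
            return "CC"
        if low in _PRONOUNS:
            return "PRP"
        if low in _VERBS:
            return "VB"
        if low in _ADVERBS:
            return "RB"
        if low in _ADJECTIVE_LEXICON:
            return "JJ"
        if any(ch.isdigit() for ch in token):
            return "NN"  # gene symbols, accession-like tokens
        if low.endswith("ly") and len(low) > 3:
            return "RB"
        if low.endswith("ing") and len(low) > 4:
            return "VBG"
        if low.endswith("ed") and len(low) > 3:
            return "VBD"
        for suffix in _ADJ_SUFFIXES:
            if low.endswith(suffix) and len(low) > len(suffix) + 2:
                return "JJ"
        if token[:1].isupper():
            return "NNP"
        return "NNS" if low.endswith("s") and not low.endswith("ss") else "NN"

    def __call__(self, tokens: Sequence[str]) -> list[str]:
        return [self._tag_one(t) for t in tokens]


def default_tagger() -> Tagger:
    return RuleBasedTagger()
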