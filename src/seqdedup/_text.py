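"""Deterministic text normalisation for record descriptions and titles.

Ships a fixed English stopword list and a small rule-based lemmatizer
(plural stripping, -ing/-ed restoration such as "encoding" -> "encode").
Both are intentionally frozen: reproducibility of the token sets matters
more than linguistic coverage for short database description lines.
"""

from __future__ import annotations

import re

__all__ = ["STOPWORDS", "lemmatize", "tokenize"]

STOPWORDS: frozenset[str] = frozenset(
    """
    a an and are as at be but by for from has have in into is it its of on
    or that the this to was were which will with
    """.split()
)

_VOWELS = set("aeiou")

_IRREGULAR = {
    "genes": "gene",
    "mrnas": "mrna",
    "species": "species",
    "analyses": "analysis",
    "sequences": "sequence",
    "sequencing": "sequence",
}


def _has_vowel(stem: str) -> bool:
    return any(c in _VOWELS or c == "y" for c in stem)


def _ends_cvc(stem: str) -> bool:
    """Consonant-vowel-consonant ending (not w/x/y), as in Porter's rule."""
    if len(stem) < 3:
        return False
    c1, v, c2 = stem[-3], stem[-2], stem[-1]
    return (
        c1 not in _VOWELS
        and v in _VOWELS
        and c2 not in _VOWELS
        and c2 not in "wxy"
    )


def _restore(stem: str) -> str:
    if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in "lsz":
        return stem[:-1]
    if _ends_cvc(stem):
        return stem + "e"
    return stem


def lemmatize(word: str) -> str:
    """Reduce one lowercase token to a base form with deterministic rules."""
    if word in _IRREGULAR:
        return _IRREGULAR[word]
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("ing") and len(word) > 5 and _has_vowel(word[:-3]):
        return _restore(word[:-3])
    if word.endswith("ed") and len(word) > 4 and _has_vowel(word[:-2]):
        return _restore(word[:-2])
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith("es") and len(word) > 3 and word[-3] in "sxzo":
        return word[:-2]
    if word.endswith("s") and not word.endswith(("ss", "us", "is")) and len(word) > 3:
        return word[:-1]
    return word


def tokenize(text: str) -> set[str]:
    """Lowercase, split on non-alphanumerics, drop stopwords, lemmatize."""
    words = re.findall(r"[a-z0-9]+", text.lower())
    return {lemmatize(w) for w in words if w not in STOPWORDS}
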