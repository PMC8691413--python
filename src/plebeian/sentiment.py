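"""Lexicon-based polarity scoring with a pluggable backend.

The built-in toy lexicon (~40 real English tokens, valences in [-3, 3])
makes the whole pipeline hermetic and deterministic. ``score_text`` sums
matched token valences and normalizes with s / sqrt(s^2 + alpha), the
standard compound normalization, so any conforming lexicon lands on the
same [-1, 1] scale. Zero lexicon hits mark a text inconclusive.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from .cleaning import clean_text
from .corpus import Corpus

logger = logging.getLogger(__name__)

#: Normalization constant for the compound score (VADER convention).
ALPHA = 15.0

_TOKEN = re.compile(r"[a-z0-9'.-]+")


@dataclass
class PolarityScore:
    """Per-text sentiment: compound on [-1, 1] plus pos/neu/neg proportions."""

    compound: float
    pos: float = 0.0
    neu: float = 0.0
    neg: float = 0.0
    inconclusive: bool = False

    def __post_init__(self) -> None:
        if not -1.0 <= self.compound <= 1.0:
            raise ValueError("compound must lie in [-1, 1]")


@dataclass
class Lexicon:
    """Map from case-folded token to valence."""

    entries: dict[str, float]
    name: str = "lexicon"

    def __post_init__(self) -> None:
        folded = {}
        for token, valence in self.entries.items():
            if not math.isfinite(valence):
                raise ValueError(f"non-finite valence for token {token!r}")
            folded[token.casefold()] = float(valence)
        self.entries = folded

    @classmethod
    def from_file(cls, path: str | Path, name: Optional[str] = None) -> "Lexicon":
        """Load a token<TAB>valence file, one entry per line."""
        path = Path(path)
        entries = {}
        for line in path.read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            token, valence = line.split("\t")
            entries[token] = float(valence)
        return cls(entries=entries, name=name or path.stem)

    @property
    def max_valence(self) -> float:
        return max(abs(v) for v in self.entries.values())


_toy_cache: Optional[Lexicon] = None


def toy_lexicon() -> Lexicon:
    """The bundled deterministic test lexicon."""
    global _toy_cache
    if _toy_cache is None:
        source = resources.files("plebeian.data").joinpath("toy_lexicon.tsv")
        entries = {}
        for line in source.read_text(encoding="utf-8").splitlines():
            if line.strip():
                token, valence = line.split("\t")
                entries[token] = float(valence)
        _toy_cache = Lexicon(entries=entries, name="toy")
    return _toy_cache


def normalize_valence_sum(s: float, alpha: float = ALPHA) -> float:
    """Map an unbounded valence sum onto (-1, 1)."""
    return s / math.sqrt(s * s + alpha)


def valence_sum_for_compound(c: float, alpha: float = ALPHA) -> float:
    """Inverse of :func:`normalize_valence_sum` (|c| < 1)."""
    return c * math.sqrt(alpha / (1.0 - c * c))


def score_text(text: str, lexicon: Optional[Lexicon] = None) -> PolarityScore:
    """Score cleaned text against a lexicon.

    The compound sign equals the sign of the matched-valence sum; zero
    matched tokens yields ``inconclusive=True`` with compound 0.
    """
    lex = lexicon or toy_lexicon()
    tokens = _TOKEN.findall(text.casefold())
    if not tokens:
        return PolarityScore(compound=0.0, inconclusive=True)

    total = 0.0
    n_pos = n_neg = n_hit = 0
    for tok in tokens:
        # trailing/leading punctuation never carries valence
        valence = lex.entries.get(tok)
        if valence is None:
            valence = lex.entries.get(tok.strip(".'-"))
        if valence is None:
            continue
        n_hit += 1
        total += valence
        if valence > 0:
            n_pos += 1
        elif valence < 0:
            n_neg += 1
    if n_hit == 0:
        return PolarityScore(compound=0.0, inconclusive=True)

    n = len(tokens)
    return PolarityScore(
        compound=normalize_valence_sum(total),
        pos=n_pos / n,
        neg=n_neg / n,
        neu=(n - n_pos - n_neg) / n,
        inconclusive=False,
    )


def score_corpus(
    corpus: Corpus,
    lexicon: Optional[Lexicon] = None,
    wordlist: Optional[frozenset[str]] = None,
) -> list[tuple[str, PolarityScore]]:
    """Clean and score every post; keep English, conclusive posts only.

    Exclusion counts (non-English, inconclusive) go to the module logger.
    """
    results: list[tuple[str, PolarityScore]] = []
    n_non_english = 0
    n_inconclusive = 0
    for post in corpus.posts():
        cleaned = clean_text(post.text, wordlist=wordlist)
        if not cleaned.english_ok:
            n_non_english += 1
            continue
        score = score_text(cleaned.text, lexicon)
        if score.inconclusive:
            n_inconclusive += 1
            continue
        results.append((post.post_id, score))
    logger.info(
        "scored %d posts (excluded %d non-English, %d inconclusive)",
        len(results),
        n_non_english,
        n_inconclusive,
    )
    return results
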