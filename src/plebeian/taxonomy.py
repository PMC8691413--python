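"""Keyword-category filtering and per-category sentiment comparison.

Three term lists ship with the package: likely-misinformation keywords,
"Locational Taxonomy" (virus names referring to places) and "Biological
Taxonomy" (official nomenclature). Matching is phrase-level,
case-insensitive and word-boundary delimited, with hyphen and period
treated as ordinary characters inside a phrase so terms like "sars-cov-2"
and "b.1.617" match as units.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .corpus import Corpus, Post, TermList
from .distribution import MIN_SAMPLE, BimodalSummary, summarize_distribution

UNFILTERED = "None"
LOCATIONAL = "Locational Taxonomy"
BIOLOGICAL = "Biological Taxonomy"
MISINFO = "Misinformation Keywords"

_BUNDLED = {
    LOCATIONAL: "terms_locational.txt",
    BIOLOGICAL: "terms_biological.txt",
    MISINFO: "terms_misinfo.txt",
}


def bundled_termlist(name: str) -> TermList:
    """Load one of the packaged term lists by category label."""
    try:
        filename = _BUNDLED[name]
    except KeyError:
        raise KeyError(f"no bundled term list named {name!r}") from None
    source = resources.files("plebeian.data").joinpath(filename)
    terms = []
    for line in source.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            terms.append(line)
    return TermList(name=name, terms=terms)


def default_categories() -> list[TermList]:
    return [bundled_termlist(LOCATIONAL), bundled_termlist(BIOLOGICAL)]


def _phrase_pattern(termlist: TermList) -> re.Pattern:
    # Boundaries: no alphanumeric character may touch either end of the
    # phrase, so "chinavirus" does not match "china virus" but a trailing
    # sentence period after "b.1.617" is fine.
    parts = [
        r"(?<![0-9a-z])" + re.escape(term) + r"(?![0-9a-z])"
        for term in termlist.terms
    ]
    return re.compile("|".join(parts))


_pattern_cache: dict[int, re.Pattern] = {}


def match_terms(text: str, termlist: TermList) -> bool:
    """True iff any phrase of the list occurs in the text on word boundaries."""
    key = id(termlist)
    pattern = _pattern_cache.get(key)
    if pattern is None:
        pattern = _phrase_pattern(termlist)
        _pattern_cache[key] = pattern
    return pattern.search(text.casefold()) is not None


def partition_corpus(
    corpus: Corpus, categories: Sequence[TermList]
) -> dict[str, list[Post]]:
    """Split the corpus posts into keyword categories.

    The "None" category holds every post; each named category holds the
    posts matching its term list. Categories are non-exclusive: a post can
    appear in several.
    """
    if not categories:
        raise ValueError("categories must be non-empty")
    all_posts = list(corpus.posts())
    out: dict[str, list[Post]] = {UNFILTERED: all_posts}
    for termlist in categories:
        out[termlist.name] = [p for p in all_posts if match_terms(p.text, termlist)]
    return out


@dataclass
class CategoryReport:
    category: str
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    summary: Optional[BimodalSummary] = None


def compare_categories(
    partition: dict[str, Sequence[float]]
) -> list[CategoryReport]:
    """Quartile/mean reports per category of compound scores.

    A full bimodal summary is attached only where the category has at least
    the KDE minimum sample (and a resolvable pair of peaks). Reports are
    sorted by category name. Quartiles use linear interpolation.
    """
    if not partition:
        raise ValueError("empty partition")
    reports = []
    for name in sorted(partition):
        scores = np.asarray(partition[name], dtype=float)
        if scores.size == 0:
            raise ValueError(f"category {name!r} has no scores")
        q1, median, q3 = np.percentile(scores, [25, 50, 75])
        summary = None
        if scores.size >= MIN_SAMPLE:
            try:
                summary, _, _ = summarize_distribution(scores)
            except ValueError:
                summary = None
        reports.append(
            CategoryReport(
                category=name,
                n=int(scores.size),
                mean=float(scores.mean()),
                median=float(median),
                q1=float(q1),
                q3=float(q3),
                summary=summary,
            )
        )
    return reports


def load_termlist(path: str | Path, name: Optional[str] = None) -> TermList:
    return TermList.from_file(path, name=name)
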