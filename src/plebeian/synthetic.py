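"""Seeded generator of synthetic social-media corpora.

Root-post sentiments follow a truncated two-Gaussian mixture on [-1, 1]
(a negative mode and a positive mode); comment sentiment echoes the root;
view counts are heavy-tailed lognormal; misinformation labels follow a
logistic link that makes negative posts more likely — but never certain —
to be misinformative. Texts are rendered from the toy lexicon so that
scoring a rendered post recovers its target compound within +-0.1, which
closes the generate -> clean -> score -> summarize loop hermetically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Optional

import numpy as np

from .corpus import Corpus, Post, Thread
from .sentiment import (
    Lexicon,
    normalize_valence_sum,
    score_text,
    toy_lexicon,
    valence_sum_for_compound,
)
from . import taxonomy

#: Rendered targets stay inside this bound; the valence sum needed for a
#: compound diverges as |c| -> 1.
TARGET_CAP = 0.99
RENDER_TOL = 0.1
MAX_TOKENS = 30

_EPOCH = datetime(2021, 1, 1, tzinfo=timezone.utc)


@dataclass
class SyntheticConfig:
    n_threads: int = 200
    neg_mode: float = -0.5
    pos_mode: float = 0.5
    mode_sd: float = 0.1
    neg_weight: float = 0.5
    comments_mean: float = 3.0
    echo_rho: float = 0.5
    views_log_mean: float = 6.0
    views_log_sd: float = 1.0
    misinfo_slope: float = 3.0
    misinfo_intercept: float = -2.0
    taxonomy_fraction: float = 0.10
    locational_bias: float = 0.35
    biological_bias: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 < self.neg_mode < 0.0 < self.pos_mode < 1.0):
            raise ValueError("modes must satisfy -1 < neg_mode < 0 < pos_mode < 1")
        if not 0.0 <= self.neg_weight <= 1.0:
            raise ValueError("neg_weight must lie in [0, 1]")
        if not 0.0 <= self.echo_rho <= 1.0:
            raise ValueError("echo_rho must lie in [0, 1]")
        if self.mode_sd <= 0:
            raise ValueError("mode_sd must be positive")


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


class _Renderer:
    """Greedy text renderer working in valence-sum space.

    Tokens are chosen so the running valence sum approaches the sum that
    normalizes to the target compound; the compound is checked analytically
    at each step, so rendering costs O(tokens) with no re-tokenization.
    """

    def __init__(self, lexicon: Lexicon):
        by_valence: dict[float, list[str]] = {}
        for token, valence in lexicon.entries.items():
            by_valence.setdefault(valence, []).append(token)
        self.valences = np.array(sorted(by_valence))
        self.tokens_by_valence = {v: sorted(t) for v, t in by_valence.items()}

    def closest_valence(self, remaining: float) -> float:
        idx = int(np.searchsorted(self.valences, remaining))
        candidates = self.valences[max(0, idx - 1): idx + 1]
        return float(min(candidates, key=lambda v: abs(remaining - v)))

    def render(self, target: float, rng: np.random.Generator) -> str:
        if not -1.0 <= target <= 1.0:
            raise ValueError("target compound must lie in [-1, 1]")
        capped = max(-TARGET_CAP, min(TARGET_CAP, target))
        s_target = valence_sum_for_compound(capped)
        s = 0.0
        words: list[str] = []
        while len(words) < MAX_TOKENS:
            if words and abs(normalize_valence_sum(s) - target) <= RENDER_TOL * 0.8:
                break
            valence = self.closest_valence(s_target - s)
            choices = self.tokens_by_valence[valence]
            words.append(choices[int(rng.integers(len(choices)))])
            s += valence
        if not words or abs(normalize_valence_sum(s) - target) > RENDER_TOL:
            raise ValueError(
                f"unreachable target {target:+.3f} with lexicon of "
                f"valences [{self.valences[0]}, {self.valences[-1]}]"
            )
        return " ".join(words)


_default_renderer: Optional[_Renderer] = None


def render_text(
    target_compound: float,
    lexicon: Optional[Lexicon] = None,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Render text whose toy-lexicon score is within +-0.1 of the target."""
    global _default_renderer
    if lexicon is None:
        if _default_renderer is None:
            _default_renderer = _Renderer(toy_lexicon())
        renderer = _default_renderer
    else:
        renderer = _Renderer(lexicon)
    if rng is None:
        rng = np.random.default_rng(0)
    return renderer.render(target_compound, rng)


def _mixture_draw(
    rng: np.random.Generator, neg_weight: float, config: SyntheticConfig
) -> float:
    """One truncated mixture draw; resampled (not clipped) into bounds."""
    for _ in range(1000):
        if rng.random() < neg_weight:
            value = rng.normal(config.neg_mode, config.mode_sd)
        else:
            value = rng.normal(config.pos_mode, config.mode_sd)
        if abs(value) <= TARGET_CAP:
            return float(value)
    raise RuntimeError("mixture truncation failed to converge")


@dataclass
class GroundTruth:
    """Per-post generation record kept out of the corpus proper."""

    target_compound: dict[str, float] = field(default_factory=dict)
    category: dict[str, str] = field(default_factory=dict)  # post_id -> tag


def generate_corpus(
    config: SyntheticConfig,
    lexicon: Optional[Lexicon] = None,
) -> tuple[Corpus, GroundTruth]:
    """Generate a labeled corpus; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    lex = lexicon or toy_lexicon()
    renderer = _Renderer(lex)
    loc_terms = taxonomy.bundled_termlist(taxonomy.LOCATIONAL).terms
    bio_terms = taxonomy.bundled_termlist(taxonomy.BIOLOGICAL).terms

    truth = GroundTruth()
    threads: list[Thread] = []
    post_counter = 0

    def next_id(prefix: str) -> str:
        nonlocal post_counter
        post_counter += 1
        return f"{prefix}{post_counter:06d}"

    def make_post(
        prefix: str,
        neg_weight: float,
        tag: Optional[str],
        parent_id: Optional[str],
        echo_target: Optional[float],
        index: int,
    ) -> Post:
        if echo_target is None:
            target = _mixture_draw(rng, neg_weight, config)
        else:
            fresh = _mixture_draw(rng, neg_weight, config)
            raw = (
                config.echo_rho * echo_target
                + (1.0 - config.echo_rho) * fresh
                + rng.normal(0.0, 0.05)
            )
            target = max(-TARGET_CAP, min(TARGET_CAP, raw))
        text = renderer.render(target, rng)
        if tag == "locational":
            text += " " + loc_terms[int(rng.integers(len(loc_terms)))]
        elif tag == "biological":
            text += " " + bio_terms[int(rng.integers(len(bio_terms)))]

        # Label from the achieved compound, not the raw target: the link is
        # to observable sentiment.
        compound = score_text(text, lex).compound
        p_misinfo = _sigmoid(
            config.misinfo_intercept + config.misinfo_slope * (-compound)
        )
        post_id = next_id(prefix)
        views = (
            max(1, int(rng.lognormal(config.views_log_mean, config.views_log_sd)))
            if parent_id is None
            else int(rng.integers(0, 50))
        )
        post = Post(
            post_id=post_id,
            text=text,
            timestamp=_EPOCH + timedelta(minutes=index),
            author_id=f"user{int(rng.integers(100_000)):05d}",
            views=views,
            parent_id=parent_id,
            platform="synthetic",
            misinfo_label=bool(rng.random() < p_misinfo),
        )
        truth.target_compound[post_id] = target
        truth.category[post_id] = tag or "none"
        return post

    for t in range(config.n_threads):
        u = rng.random()
        if u < config.taxonomy_fraction / 2:
            tag = "locational"
            weight = min(1.0, config.neg_weight + config.locational_bias)
        elif u < config.taxonomy_fraction:
            tag = "biological"
            weight = max(0.0, config.neg_weight - config.biological_bias)
        else:
            tag = None
            weight = config.neg_weight

        root = make_post("p", weight, tag, None, None, index=t * 1000)
        root_target = truth.target_compound[root.post_id]
        n_comments = int(rng.poisson(config.comments_mean))
        comments = [
            make_post(
                "c",
                weight,
                None,
                root.post_id,
                root_target,
                index=t * 1000 + i + 1,
            )
            for i in range(n_comments)
        ]
        threads.append(Thread(root=root, comments=comments))

    return Corpus(threads=threads, provenance=f"synthetic(seed={config.seed})"), truth


def user_population(n: int, seed: int = 0) -> list[str]:
    """Distinct opaque user ids for jury selection."""
    return [f"juror{seed:03d}_{i:06d}" for i in range(n)]
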