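"""Deterministic text normalization applied before sentiment scoring.

The pipeline order is part of the contract: HTML-tag stripping, URL removal,
@-handle removal, emoji-to-name replacement, whitespace collapse. The
English check is a dictionary-ratio heuristic over a bundled word list.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional

_HTML_TAG = re.compile(r"<[^<>]+>")
_URL = re.compile(r"(?:https?://\S+|\bwww\.\S+)", re.IGNORECASE)
_USERNAME = re.compile(r"@\w+")
_WHITESPACE = re.compile(r"\s+")
_TOKEN = re.compile(r"[a-z0-9']+")

# Short names for emoji commonly seen in social-media text. Anything else in
# the emoji/symbol planes is removed (still counted as a replacement).
EMOJI_NAMES: dict[str, str] = {
    "\U0001f600": "grinning face",
    "\U0001f601": "beaming face",
    "\U0001f602": "face with tears of joy",
    "\U0001f603": "grinning face with big eyes",
    "\U0001f604": "grinning face with smiling eyes",
    "\U0001f605": "grinning face with sweat",
    "\U0001f606": "grinning squinting face",
    "\U0001f609": "winking face",
    "\U0001f60a": "smiling face with smiling eyes",
    "\U0001f60d": "smiling face with heart eyes",
    "\U0001f60e": "smiling face with sunglasses",
    "\U0001f610": "neutral face",
    "\U0001f612": "unamused face",
    "\U0001f614": "pensive face",
    "\U0001f618": "face blowing a kiss",
    "\U0001f621": "pouting face",
    "\U0001f622": "crying face",
    "\U0001f62d": "loudly crying face",
    "\U0001f62e": "face with open mouth",
    "\U0001f631": "face screaming in fear",
    "\U0001f637": "face with medical mask",
    "\U0001f642": "slightly smiling face",
    "\U0001f644": "face with rolling eyes",
    "\U0001f64f": "folded hands",
    "\U0001f44d": "thumbs up",
    "\U0001f44e": "thumbs down",
    "\U0001f4aa": "flexed biceps",
    "\U0001f525": "fire",
    "\U0001f9a0": "microbe",
    "❤": "red heart",
    "❤️": "red heart",
    "\U0001f494": "broken heart",
    "\U0001f389": "party popper",
    "\U0001f480": "skull",
    "\U0001f4a9": "pile of poo",
    "\U0001f926": "person facepalming",
    "\U0001f937": "person shrugging",
}

# Codepoint ranges treated as emoji for removal of unnamed symbols.
_EMOJI_RANGES = (
    "\U0001f000-\U0001f02f"
    "\U0001f300-\U0001f5ff"
    "\U0001f600-\U0001f64f"
    "\U0001f680-\U0001f6ff"
    "\U0001f900-\U0001f9ff"
    "\U0001fa70-\U0001faff"
    "☀-➿"
    "⬀-⯿"
    "️"
)
_EMOJI = re.compile(
    "|".join(re.escape(k) for k in sorted(EMOJI_NAMES, key=len, reverse=True))
    + f"|[{_EMOJI_RANGES}]"
)


@dataclass
class CleanResult:
    text: str
    removed_url_count: int = 0
    removed_username_count: int = 0
    emoji_replacements: int = 0
    english_ok: bool = False


def clean_text(raw: str, wordlist: Optional[frozenset[str]] = None) -> CleanResult:
    """Normalize raw post text for lexicon scoring.

    Total function: empty input yields an empty result with
    ``english_ok=False``.
    """
    text = _HTML_TAG.sub(" ", raw)
    text, n_urls = _URL.subn(" ", text)
    text, n_users = _USERNAME.subn(" ", text)

    n_emoji = 0

    def _replace_emoji(m: re.Match) -> str:
        nonlocal n_emoji
        n_emoji += 1
        name = EMOJI_NAMES.get(m.group(0), "")
        return f" {name} " if name else " "

    text = _EMOJI.sub(_replace_emoji, text)
    text = _WHITESPACE.sub(" ", text).strip()
    return CleanResult(
        text=text,
        removed_url_count=n_urls,
        removed_username_count=n_users,
        emoji_replacements=n_emoji,
        english_ok=is_english(text, wordlist=wordlist),
    )


@lru_cache(maxsize=4)
def _load_wordlist(path: Optional[str]) -> frozenset[str]:
    if path is None:
        source = resources.files("plebeian.data").joinpath("english_words.txt")
        raw = source.read_text(encoding="utf-8")
    else:
        raw = Path(path).read_text(encoding="utf-8")
    words = set()
    for line in raw.splitlines():
        line = line.split("#", 1)[0].strip().lower()
        if line:
            words.add(line)
    return frozenset(words)


def default_wordlist() -> frozenset[str]:
    return _load_wordlist(None)


def load_wordlist(path: str | Path) -> frozenset[str]:
    """Load an alternate word list (one word per line, '#' comments)."""
    return _load_wordlist(str(path))


def is_english(
    text: str,
    threshold: float = 0.5,
    wordlist: Optional[frozenset[str]] = None,
) -> bool:
    """True iff the fraction of tokens found in the word list is >= threshold.

    Expects already-cleaned text; empty text is not English.
    """
    words = wordlist if wordlist is not None else default_wordlist()
    # pure-number tokens carry no language signal
    tokens = [t for t in _TOKEN.findall(text.lower()) if not t.isdigit()]
    if not tokens:
        return False
    hits = sum(1 for t in tokens if t in words)
    return hits / len(tokens) >= threshold
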