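"""Domain data model and file I/O for posts, threads, corpora, and term lists.

A :class:`Post` is a single message; a :class:`Thread` is a root post plus a
flat, ordered list of its comments (descendants at any depth are flattened);
a :class:`Corpus` is a list of threads. Corpora round-trip through JSONL
(one record per line) and CSV (header row required).
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Optional

logger = logging.getLogger(__name__)

#: Fixed record schema for JSONL/CSV corpora.
FIELD_NAMES = (
    "post_id",
    "author_id",
    "timestamp",
    "text",
    "views",
    "parent_id",
    "platform",
    "misinfo_label",
)

PLACEHOLDER_PREFIX = "__orphan_root__"


class CorpusFormatError(ValueError):
    """Raised when an input corpus file violates the record schema."""


def parse_timestamp(value: str) -> datetime:
    """Parse an ISO-8601 timestamp; zone-free values are assumed UTC."""
    ts = datetime.fromisoformat(value)
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts


@dataclass
class Post:
    """One social-media message with a view count."""

    post_id: str
    text: str
    timestamp: datetime = field(
        default_factory=lambda: datetime(1970, 1, 1, tzinfo=timezone.utc)
    )
    author_id: Optional[str] = None
    views: int = 0
    parent_id: Optional[str] = None
    platform: Optional[str] = None
    misinfo_label: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.views < 0:
            raise ValueError(f"post {self.post_id!r}: views must be >= 0")
        if self.parent_id is not None and self.parent_id == self.post_id:
            raise ValueError(f"post {self.post_id!r}: parent_id equals post_id")

    @property
    def is_root(self) -> bool:
        return self.parent_id is None

    def to_record(self) -> dict:
        rec = dataclasses.asdict(self)
        rec["timestamp"] = self.timestamp.isoformat()
        return rec


@dataclass
class Thread:
    """A root post plus the ordered, flattened list of its comments.

    ``v_act`` is the thread's actual popularity in views; it defaults to the
    root post's view count but may be overridden (e.g. when view events are
    tracked separately from the stored post).
    """

    root: Post
    comments: list[Post] = field(default_factory=list)
    v_act: Optional[int] = None

    def __post_init__(self) -> None:
        if self.v_act is None:
            self.v_act = self.root.views
        if self.v_act < 0:
            raise ValueError("v_act must be >= 0")
        ids = {self.root.post_id} | {c.post_id for c in self.comments}
        for c in self.comments:
            if c.parent_id is None or c.parent_id not in ids:
                raise ValueError(
                    f"comment {c.post_id!r}: parent_id does not resolve in thread"
                )

    @property
    def thread_id(self) -> str:
        return self.root.post_id

    @property
    def n_comments(self) -> int:
        return len(self.comments)

    def posts(self) -> Iterator[Post]:
        """Root first, then comments in stored order."""
        yield self.root
        yield from self.comments


@dataclass
class Corpus:
    threads: list[Thread] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.posts():
            if p.post_id in seen:
                raise ValueError(f"duplicate post_id {p.post_id!r} in corpus")
            seen.add(p.post_id)

    def __len__(self) -> int:
        return len(self.threads)

    def posts(self) -> Iterator[Post]:
        for t in self.threads:
            yield from t.posts()

    @property
    def n_posts(self) -> int:
        return sum(1 for _ in self.posts())


@dataclass
class TermList:
    """A named list of case-folded keyword phrases."""

    name: str
    terms: list[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"term list {self.name!r} must be non-empty")
        self.terms = [t.casefold() for t in self.terms]

    @classmethod
    def from_file(cls, path: str | Path, name: Optional[str] = None) -> "TermList":
        """Load a plain-text term list: one phrase per line, '#' comments."""
        path = Path(path)
        terms = []
        for line in path.read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                terms.append(line)
        return cls(name=name or path.stem, terms=terms)


def _coerce_record(rec: dict, lineno: int) -> Post:
    try:
        post_id = str(rec["post_id"])
        text = rec["text"]
        if text is None:
            raise KeyError("text")
        ts_raw = rec.get("timestamp") or "1970-01-01T00:00:00+00:00"
        views_raw = rec.get("views")
        views = int(views_raw) if views_raw not in (None, "") else 0
        parent = rec.get("parent_id") or None
        label_raw = rec.get("misinfo_label")
        if label_raw in (None, ""):
            label = None
        elif isinstance(label_raw, bool):
            label = label_raw
        else:
            label = str(label_raw).strip().lower() in ("true", "1", "yes")
        return Post(
            post_id=post_id,
            text=str(text),
            timestamp=parse_timestamp(ts_raw),
            author_id=rec.get("author_id") or None,
            views=views,
            parent_id=str(parent) if parent is not None else None,
            platform=rec.get("platform") or None,
            misinfo_label=label,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise CorpusFormatError(f"malformed record at line {lineno}: {exc}") from exc


def _iter_jsonl(path: Path) -> Iterator[tuple[int, dict]]:
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(
                    f"malformed record at line {lineno}: {exc}"
                ) from exc
            yield lineno, rec


def _iter_csv(path: Path) -> Iterator[tuple[int, dict]]:
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return
        for lineno, rec in enumerate(reader, start=2):
            yield lineno, rec


def assemble_threads(posts: Iterable[Post]) -> list[Thread]:
    """Group posts into threads by parent linkage.

    Comments whose parent chain cannot be resolved are attached to a
    synthetic placeholder root and reported via the module logger. Nested
    comment trees are flattened: every descendant of a root lands in that
    root's flat ``comments`` list, in input order.
    """
    posts = list(posts)
    by_id = {p.post_id: p for p in posts}

    def resolve_root(p: Post) -> Optional[str]:
        seen = set()
        cur = p
        while cur.parent_id is not None:
            if cur.post_id in seen or cur.parent_id not in by_id:
                return None
            seen.add(cur.post_id)
            cur = by_id[cur.parent_id]
        return cur.post_id

    roots = [p for p in posts if p.is_root]
    comments_of: dict[str, list[Post]] = {r.post_id: [] for r in roots}
    orphans: list[Post] = []
    for p in posts:
        if p.is_root:
            continue
        root_id = resolve_root(p)
        if root_id is None:
            orphans.append(p)
        else:
            comments_of[root_id].append(p)

    threads = [Thread(root=r, comments=comments_of[r.post_id]) for r in roots]

    for orphan in orphans:
        placeholder = Post(
            post_id=f"{PLACEHOLDER_PREFIX}{orphan.post_id}",
            text="",
            timestamp=orphan.timestamp,
            views=0,
        )
        reparented = dataclasses.replace(orphan, parent_id=placeholder.post_id)
        threads.append(Thread(root=placeholder, comments=[reparented]))
        logger.warning(
            "orphan comment %r: parent %r not found; attached to placeholder root",
            orphan.post_id,
            orphan.parent_id,
        )
    return threads


def read_corpus(path: str | Path, format: Optional[str] = None) -> Corpus:
    """Read a corpus from a JSONL or CSV file.

    ``format`` is inferred from the suffix when omitted. Raises
    :class:`CorpusFormatError` naming the offending line for malformed
    records and for duplicate post ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format {format!r}")

    records = _iter_csv(path) if format == "csv" else _iter_jsonl(path)
    posts: list[Post] = []
    seen: dict[str, int] = {}
    for lineno, rec in records:
        post = _coerce_record(rec, lineno)
        if post.post_id in seen:
            raise CorpusFormatError(
                f"duplicate post_id {post.post_id!r} at line {lineno} "
                f"(first seen at line {seen[post.post_id]})"
            )
        seen[post.post_id] = lineno
        posts.append(post)
    return Corpus(threads=assemble_threads(posts), provenance=str(path))


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as JSONL, one post record per line, threads in order."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for post in corpus.posts():
            if post.post_id.startswith(PLACEHOLDER_PREFIX):
                continue
            fh.write(json.dumps(post.to_record(), sort_keys=True) + "\n")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, datetime):
        return obj.isoformat()
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def write_summary(summary, path: str | Path) -> None:
    """Write any summary record as deterministic JSON (sorted keys).

    Two writes of equal summaries produce byte-identical files; parent
    directory must exist.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    text = json.dumps(_jsonable(summary), sort_keys=True, indent=2)
    path.write_text(text + "\n", encoding="utf-8")


def read_summary(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
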