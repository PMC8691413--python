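"""Two-phase democratic moderation with one-byte incremental thread state.

Flag Phase: threads whose popularity meets a view threshold get their root
plus a without-replacement simple random sample of comments sentiment-
averaged; a negative mean flags the thread for review.

Jury Phase: a without-replacement simple random sample of exactly
ceil(10% of viewers) users votes remove/keep; counting triggers at a vote
quorum or at the deadline, abstentions are ignored, and removal requires a
strict majority (ties keep the post). "Removal" is a feed-visibility flag,
never deletion.

Thread state compresses to a single byte: the high bit phi_d (skip flag,
high when nothing needs determination this sweep) and a 7-bit quantization
beta of the thread's mean compound sentiment. The exact running mean is
kept shadow-side between writes so the recursion never accumulates
quantization drift; beta is requantized at write time only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .corpus import Corpus, Thread
from .sentiment import PolarityScore

JURY_FRACTION = 0.10


@dataclass
class FlagConfig:
    v_thres: int
    comment_sample_size: int = 100
    negativity_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v_thres < 1:
            raise ValueError("v_thres must be >= 1")
        if self.comment_sample_size < 1:
            raise ValueError("comment_sample_size must be >= 1")


@dataclass
class FlagResult:
    thread_id: str
    eligible: bool
    sampled_comment_ids: list[str]
    mean_compound: float
    flagged: bool

    def __post_init__(self) -> None:
        if self.flagged and not self.eligible:
            raise ValueError("flagged implies eligible")
        if len(set(self.sampled_comment_ids)) != len(self.sampled_comment_ids):
            raise ValueError("sampled comment ids must be distinct")


@dataclass
class JuryConfig:
    participation_prob: float = 0.5
    deadline: float = 86400.0  # seconds of deliberation
    quorum: int = 10
    seed: int = 0
    fraction: float = JURY_FRACTION  # fixed by the panel-size law

    def __post_init__(self) -> None:
        if self.fraction != JURY_FRACTION:
            raise ValueError("jury fraction is fixed at 0.10")
        if not 0.0 <= self.participation_prob <= 1.0:
            raise ValueError("participation_prob must lie in [0, 1]")
        if self.quorum < 1:
            raise ValueError("quorum must be >= 1")


@dataclass
class Verdict:
    panel_size: int
    votes_remove: int
    votes_keep: int
    terminated_by: str  # "deadline" | "quorum"
    removed: bool

    def __post_init__(self) -> None:
        if self.votes_remove + self.votes_keep > self.panel_size:
            raise ValueError("cast votes exceed panel size")
        if self.removed and not self.votes_remove > self.votes_keep:
            raise ValueError("removal requires a strict majority")


def quantize_mean(mean: float) -> int:
    """Map a mean compound on [-1, 1] to the 7-bit code (round half up)."""
    beta = math.floor(127.0 * (mean + 1.0) / 2.0 + 0.5)
    return min(127, max(0, beta))


def dequantize(beta: int) -> float:
    """Centre of the 7-bit code's cell: inverse of :func:`quantize_mean`."""
    return 2.0 * beta / 127.0 - 1.0


@dataclass
class ThreadByte:
    """One byte of per-thread state plus its exact shadow mean."""

    phi_d: int = 1
    beta: int = 64
    shadow_mean: float = 0.0
    n_seen: int = 0

    def __post_init__(self) -> None:
        if self.phi_d not in (0, 1):
            raise ValueError("phi_d is a single bit")
        if not 0 <= self.beta <= 127:
            raise ValueError("beta must fit in 7 bits")
        if self.n_seen < 0:
            raise ValueError("n_seen must be >= 0")

    def to_byte(self) -> int:
        """Pack into one byte: skip bit in the MSB, sentiment in the rest."""
        return (self.phi_d << 7) | self.beta

    @classmethod
    def from_byte(cls, value: int, shadow_mean: float = 0.0, n_seen: int = 0) -> "ThreadByte":
        if not 0 <= value <= 255:
            raise ValueError("state must fit in one byte")
        return cls(
            phi_d=(value >> 7) & 1,
            beta=value & 0x7F,
            shadow_mean=shadow_mean,
            n_seen=n_seen,
        )


def sgn(x: float) -> int:
    return (x > 0) - (x < 0)


def _conclusive(scores: Mapping[str, PolarityScore], post_id: str) -> Optional[float]:
    s = scores.get(post_id)
    if s is None or s.inconclusive:
        return None
    return s.compound


def flag_phase(
    thread: Thread,
    scores: Mapping[str, PolarityScore],
    config: FlagConfig,
    rng: np.random.Generator,
) -> FlagResult:
    """Run the Flag Phase on one thread.

    Eligibility requires v_act >= v_thres; eligible threads get
    min(N, comment_sample_size) comments drawn without replacement, and the
    unweighted mean of the root compound and the sampled comments' compounds
    decides the flag (mean below the negativity threshold flags).
    """
    root_compound = _conclusive(scores, thread.root.post_id)
    if root_compound is None:
        raise ValueError(f"unscorable root: {thread.root.post_id!r}")

    eligible = thread.v_act >= config.v_thres
    if not eligible:
        return FlagResult(
            thread_id=thread.thread_id,
            eligible=False,
            sampled_comment_ids=[],
            mean_compound=root_compound,
            flagged=False,
        )

    n_sample = min(thread.n_comments, config.comment_sample_size)
    if n_sample > 0:
        picks = rng.choice(thread.n_comments, size=n_sample, replace=False)
        sampled_ids = [thread.comments[i].post_id for i in sorted(picks)]
    else:
        sampled_ids = []

    values = [root_compound]
    for pid in sampled_ids:
        compound = _conclusive(scores, pid)
        if compound is not None:
            values.append(compound)
    mean_compound = float(np.mean(values))
    return FlagResult(
        thread_id=thread.thread_id,
        eligible=True,
        sampled_comment_ids=sampled_ids,
        mean_compound=mean_compound,
        flagged=mean_compound < config.negativity_threshold,
    )


def panel_size_for(viewers: int) -> int:
    """Panel-size law: exactly 10% of viewers, rounded up."""
    if viewers < 1:
        raise ValueError("viewers must be >= 1")
    return math.ceil(JURY_FRACTION * viewers)


def select_jury(
    viewers: int,
    population: Sequence[str],
    rng: np.random.Generator,
) -> list[str]:
    """Without-replacement simple random sample of ceil(0.10 x viewers) users."""
    size = panel_size_for(viewers)
    if len(set(population)) != len(population):
        raise ValueError("population ids must be distinct")
    if len(population) < size:
        raise ValueError(
            f"population of {len(population)} too small for panel of {size}"
        )
    picks = rng.choice(len(population), size=size, replace=False)
    return [population[i] for i in picks]


def run_jury(
    flag: FlagResult,
    panel: Sequence[str],
    votes: Mapping[str, Optional[str]],
    config: JuryConfig,
) -> Verdict:
    """Count a jury's votes on a flagged thread.

    ``votes`` maps juror id to "remove", "keep", or None (abstain); jurors
    are never forced to vote. Counting is triggered by quorum when enough
    votes are cast, otherwise by the deadline. Removal requires a strict
    majority of cast votes; ties keep the post.
    """
    if not flag.flagged:
        raise ValueError("jury runs only on flagged threads")
    panel_set = set(panel)
    for juror in votes:
        if juror not in panel_set:
            raise ValueError(f"non-juror vote: {juror!r}")
    votes_remove = sum(1 for v in votes.values() if v == "remove")
    votes_keep = sum(1 for v in votes.values() if v == "keep")
    cast = votes_remove + votes_keep
    terminated_by = "quorum" if cast >= config.quorum else "deadline"
    return Verdict(
        panel_size=len(panel),
        votes_remove=votes_remove,
        votes_keep=votes_keep,
        terminated_by=terminated_by,
        removed=votes_remove > votes_keep,
    )


def _thread_compounds(
    thread: Thread, scores: Mapping[str, PolarityScore]
) -> list[float]:
    out = []
    for post in thread.posts():
        compound = _conclusive(scores, post.post_id)
        if compound is not None:
            out.append(compound)
    return out


def encode_thread_byte(
    thread: Thread,
    scores: Mapping[str, PolarityScore],
    v_thres: int,
    prior: Optional[ThreadByte] = None,
) -> ThreadByte:
    """Batch (re)encoding of a thread's one-byte state.

    The determination value is n_d = sgn(v_act - v_thres) * (number of posts
    not yet analyzed); phi_d goes high (skip) iff n_d <= 0 — i.e. the thread
    is unpopular, or nothing new arrived since the prior state.
    """
    compounds = _thread_compounds(thread, scores)
    n_total = len(compounds)
    n_prev = prior.n_seen if prior is not None else 0
    n_new = max(0, n_total - n_prev)
    n_d = sgn(thread.v_act - v_thres) * n_new
    shadow_mean = float(np.mean(compounds)) if compounds else 0.0
    return ThreadByte(
        phi_d=1 if n_d <= 0 else 0,
        beta=quantize_mean(shadow_mean),
        shadow_mean=shadow_mean,
        n_seen=n_total,
    )


def update_thread_byte(
    state: ThreadByte, new_scores: Iterable[float]
) -> ThreadByte:
    """Recursive state update: fold new compounds into the running mean.

    Operates on the exact shadow mean (one incremental step per score) and
    requantizes beta at the end; equals batch recomputation of the mean to
    floating-point accuracy regardless of chunking.
    """
    mean = state.shadow_mean
    n = state.n_seen
    for s in new_scores:
        n += 1
        mean += (s - mean) / n
    return ThreadByte(
        phi_d=state.phi_d,
        beta=quantize_mean(mean),
        shadow_mean=mean,
        n_seen=n,
    )


@dataclass
class SweepResult:
    state: dict[str, ThreadByte]
    flags: list[FlagResult] = field(default_factory=list)
    n_skipped: int = 0
    n_analyzed: int = 0


def interval_sweep(
    corpus: Corpus,
    state: dict[str, ThreadByte],
    scores: Mapping[str, PolarityScore],
    config: FlagConfig,
    rng: Optional[np.random.Generator] = None,
) -> SweepResult:
    """One interval pass over the corpus.

    Threads whose stored phi_d is high and that gained no posts since the
    last pass are skipped untouched. Everything else is (re)encoded — only
    the new compounds enter the running mean — and popular threads with new
    material go through the Flag Phase. Returns flag results for analyzed
    threads only; ``state`` is updated in place.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    result = SweepResult(state=state)
    for thread in corpus.threads:
        tid = thread.thread_id
        prior = state.get(tid)
        n_total = len(_thread_compounds(thread, scores))
        if prior is not None and prior.phi_d == 1 and n_total <= prior.n_seen:
            result.n_skipped += 1
            continue
        byte = encode_thread_byte(thread, scores, config.v_thres, prior=prior)
        if byte.phi_d == 0 and _conclusive(scores, thread.root.post_id) is not None:
            result.flags.append(flag_phase(thread, scores, config, rng))
            result.n_analyzed += 1
            byte.phi_d = 1  # determination done until something new arrives
        else:
            byte.phi_d = 1
            result.n_skipped += 1
        state[tid] = byte
    return result
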