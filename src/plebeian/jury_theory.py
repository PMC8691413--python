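"""Condorcet jury-theorem calculations and Monte-Carlo jury simulation.

Jurors are independent and identically competent: each votes correctly
with probability ``competence`` and participates with probability
``participation``. Majority accuracy over odd panels is the exact binomial
tail; the simulator adds optional participation and scores ties as "keep"
(the moderation tie rule) against a balanced random truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class JurorModel:
    competence: float
    participation: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.competence <= 1.0:
            raise ValueError("competence must lie in [0, 1]")
        if not 0.0 <= self.participation <= 1.0:
            raise ValueError("participation must lie in [0, 1]")


def condorcet_majority_prob(panel: int, competence: float) -> float:
    """P(majority of an odd panel is correct) — exact binomial tail.

    Even panels are rejected: a tie makes "majority correct" ambiguous (the
    operational tie rule lives in the moderation module).
    """
    if panel < 1 or panel % 2 == 0:
        raise ValueError("panel must be odd and >= 1")
    if not 0.0 <= competence <= 1.0:
        raise ValueError("competence must lie in [0, 1]")
    p = competence
    need = panel // 2 + 1
    return float(
        sum(
            math.comb(panel, k) * p**k * (1.0 - p) ** (panel - k)
            for k in range(need, panel + 1)
        )
    )


@dataclass
class AccuracyEstimate:
    accuracy: float
    std_error: float
    reps: int


def simulate_jury_accuracy(
    panel: int,
    model: JurorModel,
    reps: int = 100_000,
    seed: int = 0,
) -> AccuracyEstimate:
    """Monte-Carlo majority accuracy with optional participation.

    Each replicate draws a balanced truth (remove/keep), Bernoulli
    participation per juror, then Bernoulli correctness for participants.
    The decision is the strict majority of cast votes, ties and zero-vote
    deadlocks defaulting to "keep". Accuracy is the fraction of replicates
    whose decision matches the truth.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if panel < 1:
        raise ValueError("panel must be >= 1")
    rng = np.random.default_rng(seed)

    truth_remove = rng.random(reps) < 0.5  # True: correct decision is removal
    participates = rng.random((reps, panel)) < model.participation
    correct_vote = rng.random((reps, panel)) < model.competence

    # A participant's vote matches the truth iff their draw was "correct".
    votes_for_truth = (participates & correct_vote).sum(axis=1)
    votes_against = (participates & ~correct_vote).sum(axis=1)

    # Decision = remove iff strict majority votes remove.
    decided_remove = np.where(
        truth_remove,
        votes_for_truth > votes_against,
        votes_against > votes_for_truth,
    )
    correct = decided_remove == truth_remove
    acc = float(correct.mean())
    se = float(math.sqrt(max(acc * (1.0 - acc), 1e-12) / reps))
    return AccuracyEstimate(accuracy=acc, std_error=se, reps=reps)
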