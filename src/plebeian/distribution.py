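"""Histogram/KDE construction and bimodal summary statistics.

The sentiment distribution of a scored corpus is summarized by the
locations of its negative and positive modes (mu_minus, mu_plus), the KDE
heights there (f_minus, f_plus), and a scalar skewness gamma whose sign
says which mode dominates: gamma > 0 when the positive peak is the major
mode, gamma < 0 when it is the minor mode, gamma = 0 at equality.

The default gamma functional is ln(f_plus / f_minus); it is pluggable —
any strictly increasing-in-f_plus / decreasing-in-f_minus functional with
a zero at equality satisfies the same contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

GRID_SIZE = 512
DEFAULT_BINS = 30
MIN_SAMPLE = 10


class InsufficientSampleError(ValueError):
    pass


class NotBimodalError(ValueError):
    pass


@dataclass
class SentimentHistogram:
    bin_edges: np.ndarray  # length bins + 1, spanning [-1, 1]
    counts: np.ndarray  # length bins, non-negative integers

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_bins(self) -> int:
        return len(self.counts)


@dataclass
class KDECurve:
    grid: np.ndarray  # increasing, on [-1, 1]
    density: np.ndarray  # non-negative frequency values f(p)
    bandwidth: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def at(self, p: float) -> float:
        """Linear interpolation of the density at polarity p."""
        return float(np.interp(p, self.grid, self.density))


@dataclass
class BimodalSummary:
    mu_minus: float
    mu_plus: float
    f_minus: float
    f_plus: float
    gamma: float
    n: int
    bandwidth: float


def estimate_kde(
    scores: Sequence[float], bandwidth: Optional[float] = None
) -> KDECurve:
    """Gaussian-kernel density on a 512-point uniform grid over [-1, 1].

    Bandwidth defaults to Scott's rule. The curve is renormalized so its
    trapezoid integral over [-1, 1] is 1 (mass leaking past the score
    bounds is folded back in).
    """
    data = np.asarray(scores, dtype=float)
    if data.size < MIN_SAMPLE:
        raise InsufficientSampleError(
            f"insufficient sample: need >= {MIN_SAMPLE} scores, got {data.size}"
        )
    if np.ptp(data) == 0.0:
        raise InsufficientSampleError("insufficient sample: zero variance")
    if bandwidth is not None and bandwidth <= 0:
        raise ValueError("bandwidth must be positive")

    kde = stats.gaussian_kde(data, bw_method=bandwidth)
    # gaussian_kde's bw_method scales by the data std; report the actual
    # kernel standard deviation.
    actual_bw = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(-1.0, 1.0, GRID_SIZE)
    density = kde(grid)
    density = np.clip(density, 0.0, None)
    density /= np.trapezoid(density, grid)
    return KDECurve(grid=grid, density=density, bandwidth=actual_bw)


def find_modes(kde: KDECurve) -> tuple[float, float, float, float]:
    """Locate the negative and positive peaks of a KDE curve.

    Returns ``(mu_minus, f_minus, mu_plus, f_plus)``. Each mode must be an
    interior local maximum of its half-interval; a density that is monotone
    on either half (no interior peak) raises :class:`NotBimodalError`.
    """

    def half_mode(mask: np.ndarray, label: str) -> tuple[float, float]:
        idx = np.flatnonzero(mask)
        if idx.size < 3:
            raise NotBimodalError(f"not bimodal: no interior grid on {label} half")
        local = int(np.argmax(kde.density[idx]))
        gi = idx[local]
        if local == 0 or local == idx.size - 1:
            raise NotBimodalError(f"not bimodal: no interior peak on {label} half")
        if not (
            kde.density[gi] >= kde.density[gi - 1]
            and kde.density[gi] >= kde.density[gi + 1]
        ):
            raise NotBimodalError(f"not bimodal: no local maximum on {label} half")
        return float(kde.grid[gi]), float(kde.density[gi])

    interior = (kde.grid > -1.0) & (kde.grid < 1.0)
    mu_minus, f_minus = half_mode(interior & (kde.grid < 0.0), "negative")
    mu_plus, f_plus = half_mode(interior & (kde.grid > 0.0), "positive")
    return mu_minus, f_minus, mu_plus, f_plus


def log_ratio_gamma(f_minus: float, f_plus: float) -> float:
    """Default skewness functional: ln(f_plus / f_minus)."""
    return math.log(f_plus / f_minus)


GammaFunctional = Callable[[float, float], float]


def compute_gamma(
    f_minus: float,
    f_plus: float,
    functional: GammaFunctional = log_ratio_gamma,
) -> float:
    """Skewness from the two mode heights.

    Positive when the positive peak is the major mode, negative when it is
    the minor mode, zero at equality.
    """
    if f_minus <= 0 or f_plus <= 0:
        raise ValueError("mode heights must be positive")
    return functional(f_minus, f_plus)


def make_histogram(scores: Sequence[float], bins: int = DEFAULT_BINS) -> SentimentHistogram:
    counts, edges = np.histogram(np.asarray(scores, dtype=float), bins=bins, range=(-1.0, 1.0))
    return SentimentHistogram(bin_edges=edges, counts=counts)


def summarize_distribution(
    scores: Sequence[float],
    bins: int = DEFAULT_BINS,
    bandwidth: Optional[float] = None,
    gamma_functional: GammaFunctional = log_ratio_gamma,
) -> tuple[BimodalSummary, SentimentHistogram, KDECurve]:
    """Full pipeline: histogram + KDE + mode/skewness summary.

    Scores exactly 0 are dropped first (they are inconclusive under the
    zero-hit rule and were removed from visualization).
    """
    data = np.asarray(scores, dtype=float)
    data = data[data != 0.0]
    hist = make_histogram(data, bins=bins)
    kde = estimate_kde(data, bandwidth=bandwidth)
    mu_minus, f_minus, mu_plus, f_plus = find_modes(kde)
    gamma = compute_gamma(f_minus, f_plus, functional=gamma_functional)
    summary = BimodalSummary(
        mu_minus=mu_minus,
        mu_plus=mu_plus,
        f_minus=f_minus,
        f_plus=f_plus,
        gamma=gamma,
        n=int(data.size),
        bandwidth=kde.bandwidth,
    )
    return summary, hist, kde
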