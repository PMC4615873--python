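"""Expression-adaptive solidity thresholds.

RNA-seq coverage tracks transcript abundance, so no single k-mer count
cutoff separates errors from rare transcripts. Solidity is instead decided
locally as f(t, r) = min(g(t), h(r)):

* g(t) = alpha*t + 6*sqrt(alpha*t), the k-mer-level threshold, where t is
  the maximum multiplicity among the four possible successors at the
  current graph node and alpha is a dataset-wide variation coefficient;
* h(r) = g(x), the read-level threshold, where x is the multiplicity just
  before the first sharp (> 2-fold) drop in the read's sorted k-mer
  multiplicity curve. For reads that cannot be fixed under h(r), the
  threshold is relaxed stepwise to the next sharp drop.

alpha is calibrated from high-count k-mers: for each, the ratio of its
second-highest to highest successor multiplicity; alpha is the smallest
ratio larger than 95% of the sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .dbg import KmerTable

logger = logging.getLogger(__name__)


@dataclass
class ThresholdConfig:
    """Calibration constants for the adaptive threshold.

    alpha: explicit variation coefficient; ``None`` means "estimate from
        the table" (falling back to ``fallback_alpha`` on tiny datasets
        with no high-count k-mers).
    sample_size: how many high-count k-mers to sample for the estimate.
    high_count_cutoff: multiplicity above which a k-mer qualifies for the
        alpha sample.
    percentile: the sample quantile defining alpha (smallest ratio larger
        than this fraction of the sample).
    drop_factor: adjacent-multiplicity ratio declaring a "sharp drop" in
        the read-level curve.
    """

    alpha: Optional[float] = None
    fallback_alpha: float = 0.05
    sample_size: int = 1_000_000
    high_count_cutoff: int = 1000
    percentile: float = 0.95
    drop_factor: float = 2.0

    def __post_init__(self):
        if self.alpha is not None and not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.fallback_alpha <= 1:
            raise ValueError("fallback_alpha must be in (0, 1]")
        if not 0 < self.percentile < 1:
            raise ValueError("percentile must be in (0, 1)")
        if self.drop_factor <= 1:
            raise ValueError("drop_factor must be > 1")


def percentile_order_statistic(values: Sequence[float], percentile: float) -> float:
    """Smallest sample value larger than ``percentile`` of the sample.

    Operationalized as the 1-based order statistic floor(p*n)+1, capped at
    n: exact for distinct values and well defined under ties.
    """
    vals = sorted(values)
    n = len(vals)
    if n == 0:
        raise ValueError("empty sample")
    idx = min(int(math.floor(percentile * n)) + 1, n)
    return vals[idx - 1]


def estimate_alpha(table: KmerTable, config: ThresholdConfig, seed: int = 0) -> float:
    """Calibrate the variation coefficient alpha from high-count k-mers.

    Samples up to ``config.sample_size`` stored k-mers with multiplicity
    above ``config.high_count_cutoff`` (all of them when fewer exist;
    sampling is seeded and without replacement). For each, the ratio of
    second-highest to highest successor multiplicity is recorded, skipping
    k-mers with fewer than two nonzero successors. Returns the
    ``percentile`` order statistic of the ratios, or ``fallback_alpha``
    (with a warning log) when no ratio can be formed.
    """
    if not table.counts:
        raise ValueError("cannot estimate alpha from an empty k-mer table")
    cutoff = config.high_count_cutoff
    candidates = sorted(k for k, c in table.counts.items() if c > cutoff)
    if len(candidates) > config.sample_size:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(candidates), size=config.sample_size, replace=False)
        candidates = [candidates[i] for i in sorted(pick)]
    ratios: List[float] = []
    for kmer in candidates:
        sc = sorted(table.successor_counts(kmer).values(), reverse=True)
        if sc[1] > 0:  # at least two nonzero successors
            ratios.append(sc[1] / sc[0])
    if not ratios:
        logger.warning(
            "no high-count k-mers (> %d) with >=2 successors; "
            "falling back to alpha=%.3g", cutoff, config.fallback_alpha)
        return config.fallback_alpha
    return percentile_order_statistic(ratios, config.percentile)


def resolve_alpha(table: KmerTable, config: ThresholdConfig, seed: int = 0) -> float:
    """config.alpha when set, otherwise :func:`estimate_alpha`."""
    if config.alpha is not None:
        return config.alpha
    return estimate_alpha(table, config, seed=seed)


def kmer_level_threshold(t: float, alpha: float) -> float:
    """g(t) = alpha*t + 6*sqrt(alpha*t); 0 at t = 0, increasing in t and alpha."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    at = alpha * t
    return at + 6.0 * math.sqrt(at)


def drop_value(multiplicities: Sequence[float], drop_factor: float = 2.0,
               drop_index: int = 1) -> float:
    """x: the multiplicity before the ``drop_index``-th sharp drop.

    The positive multiplicities are sorted decreasingly m1 >= m2 >= ...;
    a drop is an adjacent pair with m_i > drop_factor * m_{i+1}. When
    fewer than ``drop_index`` drops exist, x is the minimum positive
    multiplicity (all remaining k-mers sit on one tier). An empty list
    yields 0.
    """
    if drop_index < 1:
        raise ValueError("drop_index must be >= 1")
    mults = sorted((m for m in multiplicities if m > 0), reverse=True)
    if not mults:
        return 0.0
    seen = 0
    for i in range(len(mults) - 1):
        if mults[i] > drop_factor * mults[i + 1]:
            seen += 1
            if seen == drop_index:
                return mults[i]
    return mults[-1]


def count_drops(multiplicities: Sequence[float], drop_factor: float = 2.0) -> int:
    """Number of sharp drops in the sorted positive multiplicity curve."""
    mults = sorted((m for m in multiplicities if m > 0), reverse=True)
    return sum(1 for i in range(len(mults) - 1)
               if mults[i] > drop_factor * mults[i + 1])


def read_kmer_multiplicities(read, table: KmerTable) -> List[int]:
    """Multiplicity of every k-mer window of a read, in positional order."""
    seq = (read if isinstance(read, str) else read.sequence).upper()
    k = table.k
    if len(seq) < k:
        raise ValueError(f"read shorter than k={k}")
    return [table.multiplicity(seq[i:i + k]) for i in range(len(seq) - k + 1)]


def read_level_threshold(read, table: KmerTable, config: ThresholdConfig,
                         drop_index: int = 1, alpha: Optional[float] = None) -> float:
    """h(r) = g(x) with x from :func:`drop_value` on the read's k-mers.

    ``drop_index`` > 1 selects later drops in the curve: the relaxation
    ladder for otherwise-unfixable reads. Zero-multiplicity k-mers are
    excluded from the curve.
    """
    if alpha is None:
        alpha = config.alpha
    if alpha is None:
        raise ValueError("alpha not resolved; pass alpha or set config.alpha")
    mults = read_kmer_multiplicities(read, table)
    x = drop_value(mults, config.drop_factor, drop_index)
    return kmer_level_threshold(x, alpha)


def local_threshold(t: float, h_value: float, alpha: float) -> float:
    """f(t, r) = min(g(t), h(r)): the solidity cutoff actually applied."""
    if h_value < 0:
        raise ValueError("h_value must be nonnegative")
    return min(kmer_level_threshold(t, alpha), h_value)


def pair_read_threshold(h1: float, h2: float) -> float:
    """Common threshold for a mate pair: the smaller of the two h(r)."""
    if h1 < 0 or h2 < 0:
        raise ValueError("thresholds must be nonnegative")
    return min(h1, h2)
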