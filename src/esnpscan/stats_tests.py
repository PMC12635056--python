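"""Directional allelic-imbalance test, one-sided Fisher comparisons, a
bootstrap fraction-percentile test, and log2 fold enrichment.

The allelic-imbalance rule: at a heterozygous site with at least six reads, a
gained call is imbalanced when alt/ref read ratio exceeds 1.5 and the
one-sided binomial tail probability is <= 0.01; a lost call mirrors this with
ref over alt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .io_formats import AlleleCountRecord

__all__ = [
    "AiResult",
    "binom_onesided",
    "allelic_imbalance",
    "fisher_onesided",
    "ai_fraction_comparison",
    "bootstrap_fraction_percentile",
    "log2_fold_enrichment",
]


@dataclass
class AiResult:
    """Directional allelic-imbalance verdict at one heterozygous site."""

    variant_id: str
    direction_tested: Literal["gain", "loss"]
    ratio: float
    p: float
    imbalanced: bool
    reason: Literal["ok", "low_depth", "ratio_fail", "p_fail"]


def binom_onesided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact upper-tail binomial probability P(X >= k | n, p0)."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid binomial bounds k={k}, n={n}")
    return float(stats.binom.sf(k - 1, n, p0))


def allelic_imbalance(
    record: AlleleCountRecord,
    direction: Literal["gain", "loss"],
    min_reads: int = 6,
    min_ratio: float = 1.5,
    alpha: float = 0.01,
) -> AiResult:
    """Test one het site for allele-specific signal in the called direction.

    ``gain`` tests alternate over reference reads (k = alt reads), ``loss``
    the reverse.  Total reads below ``min_reads`` short-circuits to
    low_depth; a zero denominator counts as an infinite ratio (the p-value
    still decides).
    """
    if direction not in ("gain", "loss"):
        raise ValueError(f"unknown direction {direction!r}")
    total = record.total
    if direction == "gain":
        k, other = record.alt_reads, record.ref_reads
    else:
        k, other = record.ref_reads, record.alt_reads
    ratio = math.inf if other == 0 else k / other
    if total < min_reads:
        return AiResult(record.variant_id, direction, ratio, 1.0, False, "low_depth")
    p = binom_onesided(k, total, 0.5)
    if not ratio > min_ratio:
        return AiResult(record.variant_id, direction, ratio, p, False, "ratio_fail")
    if not p <= alpha:
        return AiResult(record.variant_id, direction, ratio, p, False, "p_fail")
    return AiResult(record.variant_id, direction, ratio, p, True, "ok")


def fisher_onesided(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher's exact test on the 2x2 table [[a,b],[c,d]].

    Tests enrichment of cell ``a`` (alternative "greater").  A margin of zero
    along both rows or both columns makes the test undefined.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("Fisher test undefined for an all-zero margin")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def ai_fraction_comparison(
    fore_flags: Sequence[bool], back_flags: Sequence[bool]
) -> float:
    """One-sided Fisher probability that the foreground's imbalanced fraction
    exceeds the background's."""
    if len(fore_flags) == 0 or len(back_flags) == 0:
        raise ValueError("both flag lists must be non-empty")
    a = int(sum(fore_flags))
    b = len(fore_flags) - a
    c = int(sum(back_flags))
    d = len(back_flags) - c
    return fisher_onesided(a, b, c, d)


def bootstrap_fraction_percentile(
    pool_flags: Sequence[bool],
    m: int,
    observed_fraction: float,
    n_boot: int = 100,
    seed: int = 0,
) -> float:
    """Where an observed fraction sits among subsampled pool fractions.

    Draws ``n_boot`` without-replacement samples of size ``m`` from the pool,
    computes each sample's true-flag fraction, and returns the share of
    samples whose fraction is >= ``observed_fraction`` (the observed value's
    top percentile).
    """
    flags = np.asarray(pool_flags, dtype=bool)
    if m > flags.size:
        raise ValueError(f"sample size {m} exceeds pool size {flags.size}")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    fracs = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.choice(flags.size, size=m, replace=False)
        fracs[i] = flags[idx].mean()
    return float(np.mean(fracs >= observed_fraction))


def log2_fold_enrichment(frac_a: float, frac_b: float) -> float:
    """log2(frac_a / frac_b); frac_a = 0 returns the -inf sentinel."""
    if frac_b <= 0:
        raise ValueError(f"denominator fraction must be > 0, got {frac_b}")
    if frac_a < 0:
        raise ValueError(f"numerator fraction must be >= 0, got {frac_a}")
    if frac_a == 0:
        return -math.inf
    return math.log2(frac_a / frac_b)
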