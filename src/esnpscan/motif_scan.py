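"""PWM scanning with empirically calibrated thresholds, and eSNP motif enrichment.

Motif thresholds are calibrated the way the scanning procedure itself is
specified: scan seeded random background on both strands and take the lowest
log-odds threshold whose hit rate stays within a false-positive budget
(default: at most five hits per 10 kb).  Enrichment around eSNPs scans the
100 bp window centered on each SNP for both the reference and the alternate
allele, so a binding site present on either allele counts — avoiding allelic
bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_formats import Pwm, VariantRecord, one_hot
from .stats_tests import fisher_onesided
from .synthetic_data import simulate_genome

__all__ = [
    "MotifHit",
    "MotifEnrichment",
    "log_odds",
    "calibrate_motif_threshold",
    "scan",
    "esnp_motif_enrichment",
]


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    sequence_id: str
    offset: int  # 0-based start on the forward strand
    strand: Literal["+", "-"]
    score: float


@dataclass
class MotifEnrichment:
    motif_id: str
    fore_hit_fraction: float
    back_hit_fraction: float
    odds_ratio: float
    p: float


def log_odds(
    pwm: Pwm,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 1e-3,
) -> np.ndarray:
    """Width x 4 log2-odds matrix: log2((p + pc*bg) / ((1+pc)*bg))."""
    bg = np.asarray(background, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background frequencies must all be positive")
    return np.log2((pwm.matrix + pseudocount * bg) / ((1.0 + pseudocount) * bg))


def _window_scores(seq: str, lods: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset of one strand (empty if seq too short)."""
    w = lods.shape[0]
    if len(seq) < w:
        return np.empty(0)
    X = one_hot(seq)  # (L, 4)
    sw = sliding_window_view(X, w, axis=0)  # (L-w+1, 4, w)
    return np.einsum("obw,wb->o", sw, lods)


def scan(
    pwm: Pwm,
    seq: str,
    threshold: float,
    sequence_id: str = "",
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> list[MotifHit]:
    """All offsets on both strands scoring >= threshold (overlaps allowed).

    Minus-strand hits are reported at their forward-strand start coordinate.
    """
    lods = log_odds(pwm, background)
    lods_rc = lods[::-1, ::-1]  # scanning with the reverse-complement matrix
    hits: list[MotifHit] = []
    fwd = _window_scores(seq, lods)
    rev = _window_scores(seq, lods_rc)
    for off in np.nonzero(fwd >= threshold)[0]:
        hits.append(MotifHit(pwm.motif_id, sequence_id, int(off), "+", float(fwd[off])))
    for off in np.nonzero(rev >= threshold)[0]:
        hits.append(MotifHit(pwm.motif_id, sequence_id, int(off), "-", float(rev[off])))
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def calibrate_motif_threshold(
    pwm: Pwm,
    background_seq_total: int = 100_000,
    max_fp: float = 5.0,
    per_bp: int = 10_000,
    seed: int = 0,
    gc: float = 0.41,
) -> float:
    """Smallest log-odds threshold with <= ``max_fp`` hits per ``per_bp`` bases
    of seeded random background (both strands scanned).

    Raising the threshold can only shed hits, so the returned value is the
    minimum of a monotone family; the budget is always met on the
    calibration background itself.
    """
    if background_seq_total < 10 * per_bp:
        raise ValueError(
            f"background must span at least {10 * per_bp} bp, got "
            f"{background_seq_total}"
        )
    bg = simulate_genome(background_seq_total, gc, seed)
    lods = log_odds(pwm)
    scores = np.concatenate(
        [_window_scores(bg, lods), _window_scores(bg, lods[::-1, ::-1])]
    )
    budget = max_fp * background_seq_total / per_bp
    uniq = np.unique(scores)  # ascending
    counts = scores.size - np.searchsorted(np.sort(scores), uniq, side="left")
    ok = counts <= budget
    if not np.any(ok):
        # every observed score is too common (budget < multiplicity of the max)
        return float(np.nextafter(uniq[-1], np.inf))
    return float(uniq[ok][0])


def esnp_motif_enrichment(
    pwms: Sequence[Pwm],
    esnps: Sequence[VariantRecord],
    background_snps: Sequence[VariantRecord],
    genome: dict[str, str],
    thresholds: dict[str, float],
    flank: int = 50,
) -> list[MotifEnrichment]:
    """Per-motif enrichment of binding sites at eSNPs versus background SNPs.

    For every SNP both the reference- and alternate-allele windows of
    ``2*flank`` bp centered on the SNP are scanned; the SNP is hit-positive
    for a motif if either window carries >= 1 hit at the motif's calibrated
    threshold.  Each motif's 2x2 table (hit-positive x foreground/background)
    feeds a one-sided Fisher test; results are sorted by p.
    """
    if not esnps:
        raise ValueError("foreground eSNP set must be non-empty")

    def allele_windows(v: VariantRecord) -> list[str]:
        chrom_seq = genome[v.chrom]
        start = max(0, v.pos - flank)
        end = min(len(chrom_seq), v.pos + flank)
        ref_win = chrom_seq[start:end]
        i = v.pos - start
        alt_win = ref_win[:i] + v.alt + ref_win[i + 1 :]
        return [ref_win, alt_win]

    fore_windows = [allele_windows(v) for v in esnps]
    back_windows = [allele_windows(v) for v in background_snps]

    out: list[MotifEnrichment] = []
    for pwm in pwms:
        thr = thresholds[pwm.motif_id]

        def n_hit_positive(window_sets: list[list[str]]) -> int:
            return sum(
                1
                for wins in window_sets
                if any(scan(pwm, w, thr) for w in wins)
            )

        a = n_hit_positive(fore_windows)
        b = len(fore_windows) - a
        c = n_hit_positive(back_windows)
        d = len(back_windows) - c
        # p is undefined when no SNP anywhere (or every SNP) is hit-positive
        if (a + c == 0) or (b + d == 0):
            p = 1.0
        else:
            p = fisher_onesided(a, b, c, d)
        odds = np.inf if (b == 0 or c == 0) and a > 0 and d > 0 else (
            (a * d) / (b * c) if b > 0 and c > 0 else np.nan
        )
        out.append(
            MotifEnrichment(
                motif_id=pwm.motif_id,
                fore_hit_fraction=a / len(fore_windows),
                back_hit_fraction=(c / len(back_windows)) if back_windows else np.nan,
                odds_ratio=float(odds),
                p=p,
            )
        )
    return sorted(out, key=lambda e: e.p)
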