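"""Sliding-window ref/alt scoring, the essential window number, and eSNP calls.

A SNP's regulatory effect depends on where a putative enhancer sits relative
to it, so the scorer is applied to every window of length ``window_len``
whose center lies within ``span`` bp of the SNP, stepping by ``stride`` (21
windows at the defaults: 1 kb windows, stride 20 bp, span +/-200 bp).  For
each window the score of the reference sequence and of the same sequence with
the alternate base substituted gives a delta.  The essential window number
(EWN) counts windows where the substitution flips the window across the
activity threshold tau (inactive -> active for gain, active -> inactive for
loss).  A SNP is called a gained eSNP when deltas are positive in strictly
more than 85% of windows and EWN(gain) >= 5; lost is symmetric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .enhancer_model import SequenceScorer, score
from .io_formats import GenomicInterval, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "WindowScore",
    "EwnCall",
    "enumerate_windows",
    "window_pair_scores",
    "ewn",
    "classify",
    "scan_cohort",
]


@dataclass(frozen=True)
class WindowScore:
    """Scores for one window: reference allele, alternate allele, and their delta."""

    center_offset: int
    ref_score: float
    alt_score: float

    @property
    def delta(self) -> float:
        return self.alt_score - self.ref_score


@dataclass
class EwnCall:
    """Aggregated sliding-window verdict for one SNP."""

    variant_id: str
    n_windows: int
    n_pos_delta: int
    n_neg_delta: int
    ewn_gain: int
    ewn_loss: int
    call: Literal["gained", "lost", "none"]
    mean_delta: float


def enumerate_windows(
    snp_pos: int,
    chrom_length: int | None = None,
    window_len: int = 1000,
    stride: int = 20,
    span: int = 200,
) -> list[tuple[GenomicInterval, int]]:
    """Windows of ``window_len`` with centers at snp_pos + d, d in {-span..+span step stride}.

    Count is ``2*span/stride + 1`` when no window crosses a chromosome end;
    windows that would run past [0, chrom_length) are dropped (the caller sees
    the reduced count).
    """
    if span % stride != 0:
        raise ValueError(f"span ({span}) must be divisible by stride ({stride})")
    if window_len % 2 != 0:
        raise ValueError(f"window_len must be even, got {window_len}")
    if window_len // 2 < span:
        raise ValueError(
            f"window_len/2 ({window_len // 2}) must be >= span ({span}) so the "
            f"SNP lies inside every window"
        )
    half = window_len // 2
    out: list[tuple[GenomicInterval, int]] = []
    n_dropped = 0
    for d in range(-span, span + 1, stride):
        center = snp_pos + d
        start, end = center - half, center + half
        if start < 0 or (chrom_length is not None and end > chrom_length):
            n_dropped += 1
            continue
        out.append((GenomicInterval("*", start, end), d))
    if n_dropped:
        logger.debug("dropped %d boundary windows at pos %d", n_dropped, snp_pos)
    return out


def window_pair_scores(
    scorer: SequenceScorer,
    genome: dict[str, str] | str,
    variant: VariantRecord,
    stride: int = 20,
    span: int = 200,
) -> list[WindowScore]:
    """Score every (reference, alternate) window pair for one SNP.

    The window length is the scorer's input length.  The genome base at the
    variant position must equal the reference allele; a mismatch is an error
    (silent auto-flipping would corrupt allele orientation downstream).
    """
    chrom_seq = genome if isinstance(genome, str) else genome[variant.chrom]
    observed = chrom_seq[variant.pos]
    if observed != variant.ref:
        raise ValueError(
            f"variant {variant.id}: reference allele {variant.ref} does not "
            f"match genome base {observed} at {variant.chrom}:{variant.pos}"
        )
    windows = enumerate_windows(
        variant.pos,
        chrom_length=len(chrom_seq),
        window_len=scorer.input_len,
        stride=stride,
        span=span,
    )
    ref_seqs, alt_seqs, offsets = [], [], []
    for iv, d in windows:
        ref_window = chrom_seq[iv.start : iv.end]
        snp_i = variant.pos - iv.start
        alt_window = ref_window[:snp_i] + variant.alt + ref_window[snp_i + 1 :]
        ref_seqs.append(ref_window)
        alt_seqs.append(alt_window)
        offsets.append(d)
    if not offsets:
        return []
    ref_scores = score(scorer, ref_seqs)
    alt_scores = score(scorer, alt_seqs)
    return [
        WindowScore(d, float(r), float(a))
        for d, r, a in sorted(zip(offsets, ref_scores, alt_scores))
    ]


def ewn(
    scores: Sequence[WindowScore], tau: float, direction: Literal["gain", "loss"]
) -> int:
    """Count windows the alternate allele flips across tau.

    "Active" means score >= tau; a gain window has ref_score < tau <=
    alt_score, a loss window alt_score < tau <= ref_score.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0,1), got {tau}")
    if direction == "gain":
        return sum(1 for w in scores if w.ref_score < tau <= w.alt_score)
    if direction == "loss":
        return sum(1 for w in scores if w.alt_score < tau <= w.ref_score)
    raise ValueError(f"unknown direction {direction!r}")


def classify(
    scores: Sequence[WindowScore],
    tau: float,
    min_ewn: int = 5,
    min_consistency: float = 0.85,
    variant_id: str = "",
) -> EwnCall:
    """Gained/lost/none verdict from one SNP's window scores.

    Gained requires delta > 0 in strictly more than ``min_consistency`` of
    all windows (zero deltas count in the denominator only) and EWN(gain) >=
    ``min_ewn``; lost is symmetric.  With 21 windows the consistency bar is
    18.  The two calls are mutually exclusive by construction.
    """
    if not scores:
        raise ValueError("scores must be non-empty")
    n = len(scores)
    deltas = np.array([w.delta for w in scores])
    n_pos = int((deltas > 0).sum())
    n_neg = int((deltas < 0).sum())
    e_gain = ewn(scores, tau, "gain")
    e_loss = ewn(scores, tau, "loss")
    call: Literal["gained", "lost", "none"] = "none"
    if n_pos > min_consistency * n and e_gain >= min_ewn:
        call = "gained"
    elif n_neg > min_consistency * n and e_loss >= min_ewn:
        call = "lost"
    return EwnCall(
        variant_id=variant_id,
        n_windows=n,
        n_pos_delta=n_pos,
        n_neg_delta=n_neg,
        ewn_gain=e_gain,
        ewn_loss=e_loss,
        call=call,
        mean_delta=float(deltas.mean()),
    )


def scan_cohort(
    scorer: SequenceScorer,
    tau: float,
    genome: dict[str, str],
    variants: Sequence[VariantRecord],
    stride: int = 20,
    span: int = 200,
    min_ewn: int = 5,
    min_consistency: float = 0.85,
) -> pd.DataFrame:
    """Run the sliding-window classification over a variant set.

    Returns one row per variant (columns: id, chrom, pos, ref, alt, status,
    n_windows, n_pos_delta, n_neg_delta, ewn_gain, ewn_loss, call,
    mean_delta).  Per-variant failures (reference mismatch, too few surviving
    windows) are reported in ``status``, never silently dropped.  A variant
    is unscannable when fewer than half the expected windows survive
    chromosome-end trimming.
    """
    expected = 2 * span // stride + 1
    min_windows = expected // 2 + 1
    rows = []
    for v in variants:
        row = {
            "id": v.id, "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "status": "ok", "n_windows": 0, "n_pos_delta": 0, "n_neg_delta": 0,
            "ewn_gain": 0, "ewn_loss": 0, "call": "none", "mean_delta": np.nan,
        }
        try:
            scores = window_pair_scores(scorer, genome, v, stride=stride, span=span)
        except (ValueError, KeyError) as exc:
            row["status"] = f"error: {exc}"
            rows.append(row)
            continue
        if len(scores) < min_windows:
            row["status"] = "unscannable"
            row["n_windows"] = len(scores)
            rows.append(row)
            continue
        call = classify(scores, tau, min_ewn=min_ewn,
                        min_consistency=min_consistency, variant_id=v.id)
        row.update(
            n_windows=call.n_windows, n_pos_delta=call.n_pos_delta,
            n_neg_delta=call.n_neg_delta, ewn_gain=call.ewn_gain,
            ewn_loss=call.ewn_loss, call=call.call, mean_delta=call.mean_delta,
        )
        rows.append(row)
    n_err = sum(r["status"] != "ok" for r in rows)
    if n_err:
        logger.warning("%d/%d variants not scanned cleanly", n_err, len(rows))
    return pd.DataFrame(
        rows,
        columns=["id", "chrom", "pos", "ref", "alt", "status", "n_windows",
                 "n_pos_delta", "n_neg_delta", "ewn_gain", "ewn_loss", "call",
                 "mean_delta"],
    )
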