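"""Candidate SNP selection: allele orientation, MAF filter, F_ST ranking, dominance.

Variants are oriented so the reference allele is the major allele in the
European-ancestry (EA) panel; "common" means MAF >= 5% in at least one of the
two panels; differentiation is ranked by Wright's F_ST on the two alternate-
allele frequencies, keeping the top 5% of the non-coding, common set.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Literal, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io_formats import GenomicInterval, VariantRecord

__all__ = ["orient_to_ea_major", "wright_fst", "filter_candidates", "dominance"]

_FLIP = {"A": "A", "C": "C", "G": "G", "T": "T"}  # alleles swap, bases unchanged


def orient_to_ea_major(variant: VariantRecord) -> VariantRecord:
    """Make the EA major allele the reference allele.

    If af_ea > 0.5 the ref/alt alleles are swapped and both population
    frequencies become 1 - frequency; at af_ea == 0.5 the record is left
    unchanged.  Idempotent.
    """
    if variant.af_ea <= 0.5:
        return variant
    return replace(
        variant,
        ref=variant.alt,
        alt=variant.ref,
        af_ea=1.0 - variant.af_ea,
        af_aa=1.0 - variant.af_aa,
    )


def wright_fst(p1: float, p2: float) -> float:
    """Wright's F_ST = (H_T - H_S)/H_T for two panel allele frequencies.

    H_T = 2 p_bar (1 - p_bar) with p_bar the mean frequency; H_S is the mean
    within-population heterozygosity.  Returns 0 when H_T = 0 (both
    populations fixed for the same allele).
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"allele frequency out of [0,1]: {p}")
    p_bar = (p1 + p2) / 2.0
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    if h_t == 0.0:
        return 0.0
    h_s = p1 * (1.0 - p1) + p2 * (1.0 - p2)
    return (h_t - h_s) / h_t


def dominance(variant: VariantRecord) -> Literal["AA", "EA", "none"]:
    """Which population carries the alternate allele at higher frequency."""
    if variant.af_aa > variant.af_ea:
        return "AA"
    if variant.af_ea > variant.af_aa:
        return "EA"
    return "none"


def filter_candidates(
    variants: Sequence[VariantRecord],
    coding: Sequence[GenomicInterval],
    maf_min: float = 0.05,
    fst_top: float = 0.05,
) -> list[VariantRecord]:
    """Non-coding, common, highly differentiated candidates.

    Keeps variants that (i) do not overlap any coding interval, (ii) have MAF
    >= ``maf_min`` in EA or in AA, and (iii) rank in the top ``fst_top``
    fraction by F_ST within the set passing (i) and (ii).  Ties at the
    quantile boundary are all kept.  Returned records carry their fst and
    dominance annotations.
    """
    if not variants:
        return []
    trees: dict[str, IntervalTree] = {}
    for iv in coding:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    def maf(f: float) -> float:
        return min(f, 1.0 - f)

    stage: list[VariantRecord] = []
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is not None and tree.overlap(v.pos, v.pos + 1):
            continue
        if max(maf(v.af_ea), maf(v.af_aa)) < maf_min:
            continue
        stage.append(v)
    if not stage:
        return []
    fsts = np.array([wright_fst(v.af_ea, v.af_aa) for v in stage])
    k = int(np.ceil(len(stage) * fst_top))
    threshold = np.sort(fsts)[::-1][k - 1] if k >= 1 else np.inf
    return [
        replace(v, fst=float(f), dominance=dominance(v))
        for v, f in zip(stage, fsts)
        if f >= threshold
    ]
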