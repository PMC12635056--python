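"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the method assumes: enhancer
sequences are background DNA carrying transcription-factor motif instances;
candidate SNPs either destroy a planted motif instance ("loss"), complete a
one-mismatch instance ("gain"), or fall in background ("neutral"); het-site
read counts are binomial given a Poisson depth; case/control cohorts follow a
liability-threshold model over risk-allele dosages.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import BASE_ORDER, AlleleCountRecord, Pwm, VariantRecord

__all__ = [
    "SimConfig",
    "default_motifs",
    "simulate_genome",
    "simulate_enhancer_dataset",
    "simulate_variants",
    "simulate_allele_counts",
    "simulate_cohort",
]


def _sharp_pwm(motif_id: str, consensus: str, p_major: float = 0.97) -> Pwm:
    """Build a PWM concentrated on a consensus string."""
    minor = (1.0 - p_major) / 3.0
    mat = np.full((len(consensus), 4), minor)
    for i, b in enumerate(consensus):
        mat[i, BASE_ORDER.index(b)] = p_major
    return Pwm(motif_id, mat)


def default_motifs() -> list[Pwm]:
    """Two high-information 12-bp motifs used throughout the synthetic benchmark.

    SIM_FKH echoes a forkhead-like core (TGTTTAC), SIM_HBX a homeobox-like
    TAAT core; both are padded to 12 bp so a single-base change moves the
    log-odds score by several bits.  Columns are sharp (0.995 on the
    consensus base) because the benchmark's premise is that one substitution
    creates or destroys a functional site.
    """
    return [
        _sharp_pwm("SIM_FKH", "CATGTTTACATA", 0.995),
        _sharp_pwm("SIM_HBX", "GCTAATTAGCAG", 0.995),
    ]


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark (defaults are the conditions
    every end-to-end test and the acceptance run use)."""

    seed: int
    genome_length: int = 200_000
    gc: float = 0.41  # human-like background
    n_pos: int = 600
    n_neg: int = 5000  # heavy negative excess, mirroring the training-set imbalance
    seq_len: int = 200  # desk-scale model input length
    motifs: list[Pwm] = field(default_factory=default_motifs)
    n_variants: int = 60
    aa_dominant_frac: float = 0.7
    imbalance_effect: float = 0.8
    depth: float = 30.0
    n_case: int = 500
    n_control: int = 500
    effect_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValueError(f"gc must be in (0,1), got {self.gc}")
        if not 0.0 < self.imbalance_effect < 1.0:
            raise ValueError("imbalance_effect must be in (0,1)")
        for name in ("genome_length", "n_pos", "n_neg", "seq_len", "n_variants",
                     "n_case", "n_control"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_genome(length: int, gc: float, seed: int) -> str:
    """I.i.d. background DNA with the requested GC fraction (split equally G/C)."""
    if length <= 0:
        raise ValueError(f"length must be > 0, got {length}")
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be in (0,1), got {gc}")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASE_ORDER), size=length, p=p))


def _sample_motif_instance(pwm: Pwm, rng: np.random.Generator) -> str:
    idx = [rng.choice(4, p=row) for row in pwm.matrix]
    return "".join(BASE_ORDER[i] for i in idx)


def simulate_enhancer_dataset(
    n_pos: int,
    n_neg: int,
    motifs: list[Pwm],
    seq_len: int,
    seed: int,
    gc: float = 0.41,
    hard_negative_frac: float = 0.3,
) -> tuple[list[str], np.ndarray]:
    """Labeled sequences: positives carry 1-3 motif instances, negatives don't.

    Returns (sequences, labels) with labels 1 for the first ``n_pos`` entries.
    Positive instances are sampled from the PWM and placed uniformly on a
    random strand.  A ``hard_negative_frac`` share of negatives carries a
    one-mismatch (broken) motif instance, emulating the near-motif sequence
    that accessible-chromatin negatives from other tissues contain; this is
    what forces the learned activity boundary to sit between a broken and an
    intact site, the premise of single-base gain/loss calls.  The remaining
    negatives are plain background.
    """
    if not motifs:
        raise ValueError("motif list must be non-empty")
    max_w = max(p.width for p in motifs)
    if seq_len < max_w + 20:
        raise ValueError(f"seq_len must be >= max motif width + 20 ({max_w + 20})")
    rng = np.random.default_rng(seed)
    base_p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = list(BASE_ORDER)

    def background(n: int) -> str:
        return "".join(rng.choice(bases, size=n, p=base_p))

    def place(seq: list[str], inst: str) -> None:
        start = rng.integers(0, seq_len - len(inst) + 1)
        seq[start : start + len(inst)] = inst

    seqs: list[str] = []
    from .io_formats import revcomp

    for _ in range(n_pos):
        seq = list(background(seq_len))
        # most enhancers carry a single strong site; multi-site ones are rarer
        n_inst = rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1])
        for _ in range(n_inst):
            pwm = motifs[rng.integers(len(motifs))]
            inst = _sample_motif_instance(pwm, rng)
            if rng.random() < 0.5:
                inst = revcomp(inst)
            place(seq, inst)
        seqs.append("".join(seq))
    for _ in range(n_neg):
        seq = list(background(seq_len))
        if rng.random() < hard_negative_frac:
            pwm = motifs[rng.integers(len(motifs))]
            inst = list(pwm.consensus)
            col = rng.integers(pwm.width)
            inst[col] = rng.choice([b for b in BASE_ORDER if b != inst[col]])
            broken = "".join(inst)
            if rng.random() < 0.5:
                broken = revcomp(broken)
            place(seq, broken)
        seqs.append("".join(seq))
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    return seqs, labels


def _least_likely_base(pwm: Pwm, col: int) -> str:
    return BASE_ORDER[int(pwm.matrix[col].argmin())]


def simulate_variants(
    genome: str,
    motifs: list[Pwm],
    n: int,
    seed: int,
    aa_dominant_frac: float = 0.7,
    chrom: str = "chr1",
    margin: int = 400,
) -> tuple[str, list[VariantRecord], list[str]]:
    """Plant motif instances and SNPs that create/destroy them.

    Returns ``(genome_with_planted_instances, variants, truth_labels)`` where
    truth labels cycle through ``gain`` / ``loss`` / ``neutral``:

    * ``loss`` — the genome carries a consensus motif instance; the SNP's
      reference allele is the consensus base at the motif's most informative
      column and the alternate allele is the least-likely base there.
    * ``gain`` — the genome carries a one-mismatch instance (the least-likely
      base at that column); the alternate allele restores the consensus.
    * ``neutral`` — background position, alternate allele random.

    Sites are spaced ``2*margin`` bp apart so sliding windows never overlap
    two planted constructs.  Allele frequencies are drawn with
    ``aa_dominant_frac`` of variants AA-dominant (af_aa > af_ea), all oriented
    EA-major (af_ea <= 0.5).
    """
    if not motifs:
        raise ValueError("motif list must be non-empty")
    rng = np.random.default_rng(seed)
    spacing = 2 * margin
    n_slots = (len(genome) - 2 * margin) // spacing
    if n > n_slots:
        raise ValueError(
            f"cannot place {n} variants: only {n_slots} non-overlapping slots "
            f"in a {len(genome)} bp genome at margin {margin}"
        )
    slot_ids = rng.choice(n_slots, size=n, replace=False)
    classes = ["gain", "loss", "neutral"]
    genome_arr = list(genome)
    variants: list[VariantRecord] = []
    truth: list[str] = []
    for i, slot in enumerate(sorted(slot_ids)):
        label = classes[i % 3]
        center = margin + slot * spacing + rng.integers(0, spacing // 4)
        pwm = motifs[rng.integers(len(motifs))]
        info = (pwm.matrix * np.log2(pwm.matrix * 4 + 1e-12)).sum(axis=1)
        col = int(info.argmax())
        consensus = pwm.consensus
        if label == "neutral":
            pos = center
            ref = genome_arr[pos]
            alt = rng.choice([b for b in BASE_ORDER if b != ref])
        else:
            start = center - col  # SNP column lands on `center`
            inst = list(consensus)
            if label == "gain":
                inst[col] = _least_likely_base(pwm, col)
            genome_arr[start : start + pwm.width] = inst
            pos = center
            ref = inst[col]
            alt = consensus[col] if label == "gain" else _least_likely_base(pwm, col)
        af_ea = float(rng.uniform(0.05, 0.5))
        if rng.random() < aa_dominant_frac:
            af_aa = float(min(af_ea + rng.uniform(0.2, 0.45), 0.95))
        else:
            af_aa = float(max(af_ea - rng.uniform(0.05, 0.2), 0.01))
        variants.append(
            VariantRecord(
                id=f"sim{i}", chrom=chrom, pos=int(pos), ref=str(ref), alt=str(alt),
                af_ea=af_ea, af_aa=af_aa,
            )
        )
        truth.append(label)
    return "".join(genome_arr), variants, truth


def simulate_allele_counts(
    n_sites: int, depth: float, imbalance_effect: float, seed: int
) -> list[AlleleCountRecord]:
    """Het-site read counts: total ~ Poisson(depth) truncated >= 1,
    alt ~ Binomial(total, imbalance_effect)."""
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if not 0.0 < imbalance_effect < 1.0:
        raise ValueError("imbalance_effect must be in (0,1)")
    rng = np.random.default_rng(seed)
    totals = rng.poisson(depth, size=n_sites)
    while np.any(totals == 0):  # zero-truncation by redraw
        zeros = totals == 0
        totals[zeros] = rng.poisson(depth, size=int(zeros.sum()))
    alts = rng.binomial(totals, imbalance_effect)
    return [
        AlleleCountRecord(f"site{i}", int(t - a), int(a))
        for i, (t, a) in enumerate(zip(totals, alts))
    ]


def simulate_cohort(
    n_case: int,
    n_control: int,
    variants: list[VariantRecord],
    effect_weights: np.ndarray,
    seed: int,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Liability-threshold case/control cohort over risk-allele dosages.

    Each individual is assigned one of the two populations (equal split);
    dosages at variant *j* are Binomial(2, af) at that population's
    alternate-allele frequency.  Liability = dosages @ effect_weights +
    N(0, noise_sd); the top ``n_case`` liabilities are cases.

    Returns ``(dosages, labels, populations)`` with dosages shaped
    (n_case + n_control) x len(variants), labels in {0,1}, populations in
    {"EA", "AA"}.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("cohort sizes must be positive")
    effect_weights = np.asarray(effect_weights, dtype=float)
    if effect_weights.size > len(variants):
        raise ValueError("more effect weights than variants")
    w = np.zeros(len(variants))
    w[: effect_weights.size] = effect_weights
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    pops = np.array(["EA", "AA"])[rng.integers(0, 2, size=n)]
    af = np.array(
        [[v.af_ea for v in variants], [v.af_aa for v in variants]]
    )  # 2 x m
    pop_idx = (pops == "AA").astype(int)
    dosages = rng.binomial(2, af[pop_idx])  # n x m
    liability = dosages @ w + rng.normal(0.0, noise_sd, size=n)
    threshold = np.partition(liability, n - n_case)[n - n_case]
    labels = (liability >= threshold).astype(int)
    # resolve ties at the threshold so exactly n_case cases are labeled
    if labels.sum() != n_case:
        order = np.argsort(-liability, kind="stable")
        labels = np.zeros(n, dtype=int)
        labels[order[:n_case]] = 1
    return dosages, labels, pops
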