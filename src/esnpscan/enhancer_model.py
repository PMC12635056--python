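"""The sequence-based enhancer activity scorer and its FPR calibration.

A convolutional network reads a one-hot-encoded window of fixed length and
emits a score in [0,1]; larger scores mean a higher propensity to be an
active tissue-specific enhancer.  A window is called "active" when its score
reaches the calibrated threshold tau, chosen so that the false-positive rate
on negative (non-enhancer) sequences stays at or below a target (1% by
default).

Positive training windows are derived from open-chromatin peaks inside
acetylation-marked regions; negatives are accessible regions from other
tissues.  At inference the reported score is the mean of the forward-strand
and reverse-complement model outputs, which makes scoring exactly
strand-symmetric.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import rankdata

from ._nn import ConvNet
from .io_formats import GenomicInterval, Pwm, one_hot, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "EnhancerScorer",
    "ScorerCalibration",
    "SequenceScorer",
    "PwmScorer",
    "build_training_regions",
    "train",
    "score",
    "calibrate_threshold",
    "auroc",
]


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters for the enhancer scorer.

    The default channel stack (320/320/240/240/480 kernels, 180 dense units)
    is the full-scale profile; ``ModelConfig.desk_scale()`` gives the reduced
    two-layer, 200 bp profile used in the synthetic benchmark.
    """

    input_len: int = 1000
    conv_channels: list[int] = field(default_factory=lambda: [320, 320, 240, 240, 480])
    kernel_width: list[int] | int = 8
    pool: list[int] | int = field(default_factory=lambda: [4, 4, 5, 5, 1])
    dense_units: int = 180
    dropout: float = 0.1
    epochs: int = 30
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.conv_channels)
        if isinstance(self.kernel_width, int):
            self.kernel_width = [self.kernel_width] * n
        if isinstance(self.pool, int):
            self.pool = [self.pool] * n
        if len(self.kernel_width) != n or len(self.pool) != n:
            raise ValueError("kernel_width/pool length must match conv_channels")
        if any(c <= 0 for c in self.conv_channels):
            raise ValueError("conv channels must be positive")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "ModelConfig":
        """Reduced architecture: 200 bp input, two conv layers, global max pool.

        The second pooling width spans the whole remaining sequence, so the
        dense head sees position-independent motif evidence — the right
        inductive bias when enhancers are defined by site presence rather
        than site position.
        """
        return cls(
            input_len=200,
            conv_channels=[32, 48],
            kernel_width=8,
            pool=[1, 186],
            dense_units=32,
            dropout=0.0,
            epochs=30,
            batch_size=128,
            learning_rate=1e-3,
            seed=seed,
        )


class SequenceScorer(Protocol):
    """Anything that maps equal-length DNA windows to activity scores in [0,1]."""

    input_len: int

    def score_sequences(self, seqs: Sequence[str]) -> np.ndarray: ...


def _encode_batch(seqs: Sequence[str], input_len: int) -> np.ndarray:
    X = np.empty((len(seqs), input_len, 4), dtype=np.float32)
    for i, s in enumerate(seqs):
        if len(s) != input_len:
            raise ValueError(
                f"sequence {i} has length {len(s)}, expected {input_len}"
            )
        X[i] = one_hot(s)
    return X


@dataclass
class ScorerCalibration:
    """Activity threshold tau calibrated to a false-positive-rate budget."""

    tau: float
    fpr: float
    empirical_fpr: float
    n_negatives_used: int


class EnhancerScorer:
    """A trained enhancer activity model (CNN over one-hot DNA windows)."""

    version = "1"

    def __init__(self, net: ConvNet, config: ModelConfig, metadata: dict | None = None):
        self._net = net
        self.config = config
        self.metadata = metadata or {}
        self.input_len = config.input_len

    def score_sequences(self, seqs: Sequence[str]) -> np.ndarray:
        """Mean of forward-strand and reverse-complement outputs, in [0,1]."""
        if len(seqs) == 0:
            return np.empty(0)
        fwd = _encode_batch(seqs, self.input_len)
        rev = _encode_batch([revcomp(s) for s in seqs], self.input_len)
        return 0.5 * (self._net.predict(fwd) + self._net.predict(rev))

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "config.json", "w") as fh:
            json.dump(
                {"config": asdict(self.config), "metadata": self.metadata,
                 "version": self.version},
                fh, indent=2,
            )
        np.savez(directory / "weights.npz", **self._net.state_dict())

    @classmethod
    def load(cls, directory: str | Path) -> "EnhancerScorer":
        directory = Path(directory)
        with open(directory / "config.json") as fh:
            blob = json.load(fh)
        config = ModelConfig(**blob["config"])
        net = _build_net(config)
        with np.load(directory / "weights.npz") as state:
            net.load_state_dict(dict(state))
        return cls(net, config, blob.get("metadata"))


def _build_net(config: ModelConfig) -> ConvNet:
    return ConvNet(
        input_len=config.input_len,
        channels=config.conv_channels,
        kernels=list(config.kernel_width),
        pools=list(config.pool),
        dense_units=config.dense_units,
        dropout=config.dropout,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# training-region construction
# ---------------------------------------------------------------------------

def build_training_regions(
    h3k27ac: Sequence[GenomicInterval],
    dhs: Sequence[GenomicInterval],
    promoters: Sequence[GenomicInterval],
    genome: dict[str, str],
    window_len: int = 1000,
) -> list[str]:
    """Positive enhancer windows from acetylation + open-chromatin peaks.

    Open-chromatin (DHS) peaks overlapping the same broad acetylation peak are
    merged into one interval; that interval's center defines a ``window_len``
    window.  Windows overlapping any promoter interval, or running off a
    chromosome end, are dropped.  Each retained window is emitted with its
    reverse complement.
    """
    dhs_trees: dict[str, IntervalTree] = {}
    for iv in dhs:
        dhs_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    prom_trees: dict[str, IntervalTree] = {}
    for iv in promoters:
        prom_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    half = window_len // 2
    seqs: list[str] = []
    n_dropped_prom = n_dropped_edge = 0
    for peak in h3k27ac:
        tree = dhs_trees.get(peak.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(peak.start, peak.end))
        if not hits:
            continue
        merged_start = min(h.begin for h in hits)
        merged_end = max(h.end for h in hits)
        center = (merged_start + merged_end) // 2
        start, end = center - half, center + half
        chrom_seq = genome.get(peak.chrom)
        if chrom_seq is None or start < 0 or end > len(chrom_seq):
            n_dropped_edge += 1
            continue
        ptree = prom_trees.get(peak.chrom)
        if ptree is not None and ptree.overlap(start, end):
            n_dropped_prom += 1
            continue
        s = chrom_seq[start:end]
        seqs.append(s)
        seqs.append(revcomp(s))
    logger.info(
        "built %d positive windows (%d dropped on promoters, %d on edges)",
        len(seqs), n_dropped_prom, n_dropped_edge,
    )
    return seqs


# ---------------------------------------------------------------------------
# training / scoring / calibration
# ---------------------------------------------------------------------------

def train(
    pos_seqs: Sequence[str],
    neg_seqs: Sequence[str],
    config: ModelConfig,
    seed: int | None = None,
    augment_revcomp: bool = True,
) -> EnhancerScorer:
    """Train the scorer on labeled windows with a seeded 70/15/15 split.

    Reverse-complement augmentation is applied symmetrically to both classes.
    Early stopping (patience 5) monitors validation loss; split sizes and
    final losses are recorded in the scorer's metadata.
    """
    if seed is None:
        seed = config.seed
    if len(pos_seqs) < 20 or len(neg_seqs) < 20:
        raise ValueError(
            f"need >= 20 sequences per class to split 70/15/15, got "
            f"{len(pos_seqs)} positives / {len(neg_seqs)} negatives"
        )
    if augment_revcomp:
        pos_seqs = list(pos_seqs) + [revcomp(s) for s in pos_seqs]
        neg_seqs = list(neg_seqs) + [revcomp(s) for s in neg_seqs]
    X = _encode_batch(list(pos_seqs) + list(neg_seqs), config.input_len)
    y = np.concatenate([np.ones(len(pos_seqs)), np.zeros(len(neg_seqs))])

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    X, y = X[order], y[order]
    n = len(y)
    n_train, n_val = int(0.70 * n), int(0.15 * n)
    X_tr, y_tr = X[:n_train], y[:n_train]
    X_val, y_val = X[n_train : n_train + n_val], y[n_train : n_train + n_val]
    X_te, y_te = X[n_train + n_val :], y[n_train + n_val :]

    net = _build_net(config)
    info = net.fit(
        X_tr, y_tr, X_val, y_val,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        patience=5,
        seed=seed,
    )
    test_scores = net.predict(X_te)
    test_auroc = auroc(test_scores[y_te == 1], test_scores[y_te == 0])
    metadata = {
        "n_train": int(n_train),
        "n_val": int(n_val),
        "n_test": int(n - n_train - n_val),
        "best_val_loss": info["best_val_loss"],
        "best_epoch": info["best_epoch"],
        "test_auroc": float(test_auroc),
        "seed": int(seed),
    }
    logger.info("training done: %s", metadata)
    return EnhancerScorer(net, config, metadata)


def score(scorer: SequenceScorer, seqs: Sequence[str]) -> np.ndarray:
    """Score a batch of windows (thin functional wrapper over the scorer)."""
    return scorer.score_sequences(seqs)


def calibrate_threshold(
    scorer: SequenceScorer, neg_seqs: Sequence[str], fpr: float = 0.01
) -> ScorerCalibration:
    """tau = smallest observed negative score with FPR(tau) <= the budget.

    Requires at least ``1/fpr`` negatives so the empirical FPR has resolution
    at the budget.
    """
    n = len(neg_seqs)
    min_n = int(np.ceil(1.0 / fpr))
    if n < min_n:
        raise ValueError(
            f"need at least {min_n} negative sequences to calibrate at "
            f"FPR {fpr}, got {n}"
        )
    scores = np.asarray(score(scorer, neg_seqs))
    uniq = np.unique(scores)  # ascending
    # count of scores >= v for each candidate v
    counts = n - np.searchsorted(np.sort(scores), uniq, side="left")
    ok = counts <= fpr * n
    tau = float(uniq[ok][0])  # smallest qualifying observed value
    emp = float(counts[ok][0] / n)
    return ScorerCalibration(tau=tau, fpr=fpr, empirical_fpr=emp, n_negatives_used=n)


def auroc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """P(random positive outranks random negative), ties counted 0.5."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


# ---------------------------------------------------------------------------
# PWM baseline scorer
# ---------------------------------------------------------------------------

class PwmScorer:
    """Deterministic motif-match scorer: logistic of the best log-odds hit.

    A transparent baseline/oracle with the same interface as the trained
    model: score = sigmoid((best hit score over all offsets and strands -
    midpoint) / scale), so windows containing a strong motif instance score
    near 1 and background near 0.
    """

    def __init__(self, pwms: Sequence[Pwm], input_len: int, scale: float = 2.0,
                 midpoint: float | None = None):
        from .motif_scan import log_odds

        self.input_len = input_len
        self.scale = scale
        self._lods = [log_odds(p) for p in pwms]
        self._lods += [log_odds(p.reverse_complement()) for p in pwms]
        if midpoint is None:
            # halfway between a perfect match and zero, over all motifs
            midpoint = 0.5 * max(m.max(axis=1).sum() for m in self._lods)
        self.midpoint = midpoint

    def score_sequences(self, seqs: Sequence[str]) -> np.ndarray:
        out = np.empty(len(seqs))
        for i, s in enumerate(seqs):
            if len(s) != self.input_len:
                raise ValueError(f"sequence {i} has length {len(s)}, "
                                 f"expected {self.input_len}")
            X = one_hot(s)
            best = -np.inf
            for m in self._lods:
                w = m.shape[0]
                if len(s) < w:
                    continue
                sw = np.lib.stride_tricks.sliding_window_view(X, w, axis=0)
                vals = np.einsum("obw,wb->o", sw, m)
                best = max(best, float(vals.max()))
            out[i] = 1.0 / (1.0 + np.exp(-(best - self.midpoint) / self.scale))
        return out
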