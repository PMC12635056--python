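"""Shared fixtures.

The expensive artifacts (the trained desk-scale scorer and its calibration)
are session-scoped and built once from the default study conditions; every
test that needs a trained model shares them.
"""

from __future__ import annotations

import numpy as np
import pytest

from esnpscan import enhancer_model as em
from esnpscan import synthetic_data as sd

#: Seed for every session-scoped artifact.
SESSION_SEED = 7


@pytest.fixture(scope="session")
def sim_config() -> sd.SimConfig:
    return sd.SimConfig(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def motifs(sim_config):
    return sim_config.motifs


@pytest.fixture(scope="session")
def enhancer_dataset(sim_config):
    """Default-condition labeled training sequences (positives first)."""
    cfg = sim_config
    seqs, labels = sd.simulate_enhancer_dataset(
        cfg.n_pos, cfg.n_neg, cfg.motifs, cfg.seq_len, cfg.seed + 2, gc=cfg.gc
    )
    return seqs, labels


@pytest.fixture(scope="session")
def trained_scorer(sim_config, enhancer_dataset):
    """Desk-scale CNN trained once on the default synthetic conditions."""
    seqs, labels = enhancer_dataset
    pos = [s for s, l in zip(seqs, labels) if l == 1]
    neg = [s for s, l in zip(seqs, labels) if l == 0]
    config = em.ModelConfig.desk_scale(seed=sim_config.seed)
    return em.train(pos, neg, config, seed=sim_config.seed)


@pytest.fixture(scope="session")
def calibration(sim_config, trained_scorer):
    """tau at FPR <= 1% on fresh negatives from the same generator."""
    cfg = sim_config
    neg_cal, _ = sd.simulate_enhancer_dataset(
        0, 1500, cfg.motifs, cfg.seq_len, cfg.seed + 10, gc=cfg.gc
    )
    return em.calibrate_threshold(trained_scorer, neg_cal, fpr=0.01)


@pytest.fixture(scope="session")
def planted_genome(sim_config):
    """(genome, variants, truth) with gain/loss/neutral SNPs planted."""
    cfg = sim_config
    genome = sd.simulate_genome(cfg.genome_length, cfg.gc, cfg.seed)
    return sd.simulate_variants(
        genome, cfg.motifs, cfg.n_variants, cfg.seed + 1,
        aa_dominant_frac=cfg.aa_dominant_frac,
    )


@pytest.fixture(scope="session")
def pwm_scorer(motifs):
    """Deterministic motif-presence oracle with the scorer interface."""
    return em.PwmScorer(motifs, input_len=200)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
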