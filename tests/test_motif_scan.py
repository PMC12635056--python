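"""PWM log-odds scanning, threshold calibration, and eSNP motif enrichment."""

import numpy as np
import pytest

from esnpscan import motif_scan as ms
from esnpscan import synthetic_data as sd
from esnpscan.io_formats import Pwm, VariantRecord, one_hot, revcomp


@pytest.fixture(scope="module")
def pwm(motifs):
    return motifs[0]


class TestLogOdds:
    def test_uniform_column_near_zero(self):
        p = Pwm("u", np.full((5, 4), 0.25))
        assert np.allclose(ms.log_odds(p), 0.0, atol=0.01)

    def test_sign_structure(self):
        mat = np.tile([0.997, 0.001, 0.001, 0.001], (4, 1))
        lo = ms.log_odds(Pwm("a", mat))
        assert np.all(lo[:, 0] > 0) and np.all(lo[:, 1:] < -5)

    def test_zero_pseudocount_closed_form(self):
        mat = np.tile([0.4, 0.3, 0.2, 0.1], (4, 1))
        lo = ms.log_odds(Pwm("p", mat), pseudocount=0.0)
        np.testing.assert_allclose(lo, np.log2(mat / 0.25))

    def test_zero_background_rejected(self, pwm):
        with pytest.raises(ValueError):
            ms.log_odds(pwm, background=(0.5, 0.5, 0.0, 0.0))


class TestScan:
    def test_planted_consensus_single_hit(self, pwm, rng):
        bg = "".join(rng.choice(list("ACGT"), 200))
        seq = bg[:90] + pwm.consensus + bg[90 + pwm.width:]
        lo = ms.log_odds(pwm)
        high = lo.max(axis=1).sum() - 1.0
        hits = ms.scan(pwm, seq, high)
        assert len(hits) == 1
        assert (hits[0].offset, hits[0].strand) == (90, "+")

    def test_strand_symmetry(self, pwm, rng):
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), 100))
            fwd = ms.scan(pwm, seq, 5.0)
            rev = ms.scan(pwm, revcomp(seq), 5.0)
            assert len(fwd) == len(rev)
            assert sorted(h.strand for h in fwd) == sorted(
                {"+": "-", "-": "+"}[h.strand] for h in rev
            )

    def test_infinite_threshold_no_hits(self, pwm):
        assert ms.scan(pwm, pwm.consensus * 3, np.inf) == []

    def test_short_sequence_empty(self, pwm):
        assert ms.scan(pwm, "ACGT", 0.0) == []

    def test_agrees_with_bruteforce_offsets(self, pwm, rng):
        seq = "".join(rng.choice(list("ACGT"), 150))
        lo = ms.log_odds(pwm)
        threshold = 3.0
        hits = ms.scan(pwm, seq, threshold)
        # brute force: score each offset on each strand explicitly
        brute = []
        for strand, mat in (("+", lo), ("-", lo[::-1, ::-1])):
            for off in range(len(seq) - pwm.width + 1):
                window = one_hot(seq[off : off + pwm.width])
                s = float((window * mat).sum())
                if s >= threshold:
                    brute.append((off, strand, round(s, 9)))
        assert sorted((h.offset, h.strand, round(h.score, 9)) for h in hits) == sorted(
            brute
        )


class TestCalibration:
    def test_budget_met_on_calibration_background(self, pwm):
        thr = ms.calibrate_motif_threshold(pwm, 100_000, max_fp=5, seed=3)
        bg = sd.simulate_genome(100_000, 0.41, 3)
        n_hits = len(ms.scan(pwm, bg, thr))
        assert n_hits <= 5 * 100_000 / 10_000

    def test_budget_met_on_heldout_background(self, pwm):
        thr = ms.calibrate_motif_threshold(pwm, 100_000, max_fp=5, seed=4)
        held = sd.simulate_genome(100_000, 0.41, 999)
        rate = len(ms.scan(pwm, held, thr)) / 10  # hits per 10 kb
        assert rate <= 1.2 * 5

    def test_lax_budget_gives_minimum_score(self, pwm):
        # budget of 3 hits/bp exceeds every possible hit (2 strands ~ 2/bp)
        thr = ms.calibrate_motif_threshold(pwm, 100_000, max_fp=30_000, seed=5)
        bg = sd.simulate_genome(100_000, 0.41, 5)
        lo = ms.log_odds(pwm)
        all_scores = np.concatenate(
            [ms._window_scores(bg, lo), ms._window_scores(bg, lo[::-1, ::-1])]
        )
        assert thr == pytest.approx(all_scores.min())

    def test_threshold_monotone_in_budget(self, pwm):
        thresholds = [
            ms.calibrate_motif_threshold(pwm, 100_000, max_fp=fp, seed=6)
            for fp in (50, 20, 5, 1)
        ]
        assert all(a <= b for a, b in zip(thresholds, thresholds[1:]))

    def test_insufficient_background_rejected(self, pwm):
        with pytest.raises(ValueError):
            ms.calibrate_motif_threshold(pwm, 50_000, seed=1)


@pytest.fixture(scope="module")
def setup(motifs):
    genome = sd.simulate_genome(200_000, 0.41, 31)
    genome, variants, truth = sd.simulate_variants(genome, motifs, 60, seed=32)
    thresholds = {
        p.motif_id: ms.calibrate_motif_threshold(p, seed=33) for p in motifs
    }
    return genome, variants, truth, thresholds


class TestEnrichment:
    def test_motif_snps_enriched_over_background(self, motifs, setup):
        genome, variants, truth, thresholds = setup
        fore = [v for v, t in zip(variants, truth) if t in ("gain", "loss")]
        back = [v for v, t in zip(variants, truth) if t == "neutral"]
        out = ms.esnp_motif_enrichment(
            motifs, fore, back, {"chr1": genome}, thresholds
        )
        assert out[0].p < 1e-4
        assert out[0].fore_hit_fraction > out[0].back_hit_fraction

    def test_null_foreground_not_enriched(self, motifs, setup):
        genome, variants, truth, thresholds = setup
        back = [v for v, t in zip(variants, truth) if t == "neutral"]
        out = ms.esnp_motif_enrichment(
            motifs, back, back, {"chr1": genome}, thresholds
        )
        for e in out:
            assert e.p > 0.4  # identical sets cannot be enriched

    def test_alt_only_hit_counts(self, motifs):
        """A motif present only on the alternate allele still marks the SNP."""
        pwm = motifs[0]
        rng = np.random.default_rng(71)
        bg = "".join(rng.choice(list("ACGT"), 400))
        cons = pwm.consensus
        # plant a one-mismatch instance; the SNP's alt restores the consensus
        col = 5
        broken = cons[:col] + ("A" if cons[col] != "A" else "C") + cons[col + 1:]
        pos = 200
        genome = bg[: pos - col] + broken + bg[pos - col + pwm.width:]
        snp = VariantRecord("g", "chr1", pos, genome[pos], cons[col], 0.1, 0.4)
        neutral = VariantRecord("n", "chr1", 100, genome[100],
                                "A" if genome[100] != "A" else "C", 0.1, 0.4)
        # consensus-level threshold: only the intact (alt) site can hit
        thr = {p.motif_id: ms.log_odds(p).max(axis=1).sum() - 5.0 for p in motifs}
        out = ms.esnp_motif_enrichment(
            motifs, [snp], [neutral], {"chr1": genome}, thr
        )
        by_id = {e.motif_id: e for e in out}
        assert by_id[pwm.motif_id].fore_hit_fraction == 1.0
        assert by_id[pwm.motif_id].back_hit_fraction == 0.0

    def test_empty_foreground_rejected(self, motifs, setup):
        genome, _, _, thresholds = setup
        with pytest.raises(ValueError):
            ms.esnp_motif_enrichment(motifs, [], [], {"chr1": genome}, thresholds)

    def test_null_pvalues_superuniform_at_5pct(self, motifs):
        """Under the null the Fisher test is conservative: P(p <= 0.05) <= ~0.05."""
        genome = sd.simulate_genome(150_000, 0.41, 41)
        genome, variants, _ = sd.simulate_variants(genome, motifs, 45, seed=42)
        thresholds = {
            p.motif_id: ms.calibrate_motif_threshold(p, seed=43) for p in motifs
        }
        rng = np.random.default_rng(44)
        n_sig = 0
        n_tests = 0
        for _ in range(50):
            idx = rng.permutation(len(variants))
            fore = [variants[i] for i in idx[:15]]
            back = [variants[i] for i in idx[15:]]
            for e in ms.esnp_motif_enrichment(
                motifs, fore, back, {"chr1": genome}, thresholds
            ):
                n_tests += 1
                n_sig += e.p <= 0.05
        assert n_sig / n_tests <= 0.08  # 5% level plus sampling slack
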