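"""Sliding-window enumeration, EWN counting, and gained/lost classification."""

import numpy as np
import pytest

from esnpscan import ewn_scan
from esnpscan.ewn_scan import WindowScore, classify, enumerate_windows, ewn
from esnpscan.io_formats import VariantRecord


def ws(pairs):
    return [WindowScore(i, r, a) for i, (r, a) in enumerate(pairs)]


class TestEnumerateWindows:
    def test_default_geometry_yields_21_windows(self):
        out = enumerate_windows(10_000)
        assert len(out) == 21
        assert (out[0][0].start, out[0][0].end) == (9300, 10300)
        assert (out[-1][0].start, out[-1][0].end) == (9700, 10700)
        assert [d for _, d in out] == list(range(-200, 201, 20))

    def test_span_zero_single_window(self):
        out = enumerate_windows(5000, span=0)
        assert len(out) == 1 and out[0][1] == 0

    def test_stride50_nine_windows(self):
        assert len(enumerate_windows(10_000, stride=50, span=200)) == 9

    def test_boundary_windows_dropped(self):
        out = enumerate_windows(350, window_len=1000, stride=20, span=200)
        # centers 150..550; window [c-500, c+500) needs c >= 500
        assert all(iv.start >= 0 for iv, _ in out)
        assert len(out) == 3  # centers 500, 520, 540

    def test_span_not_divisible_rejected(self):
        with pytest.raises(ValueError):
            enumerate_windows(1000, stride=30, span=200)

    def test_snp_outside_window_rejected(self):
        with pytest.raises(ValueError):
            enumerate_windows(1000, window_len=200, stride=20, span=200)


class TestEwn:
    def test_five_window_conversion_pattern(self):
        scores = ws([(0.40, 0.70)] * 5 + [(0.40, 0.50)] * 16)
        assert ewn(scores, 0.58, "gain") == 5
        assert ewn(scores, 0.58, "loss") == 0

    def test_no_change_zero(self):
        scores = ws([(0.4, 0.4)] * 21)
        assert ewn(scores, 0.5, "gain") == 0
        assert ewn(scores, 0.5, "loss") == 0

    def test_boundary_active_means_geq_tau(self):
        # ref exactly at tau is already active: no gain conversion
        scores = ws([(0.58, 0.60)])
        assert ewn(scores, 0.58, "gain") == 0
        # alt exactly at tau counts as converted
        scores = ws([(0.40, 0.58)])
        assert ewn(scores, 0.58, "gain") == 1

    def test_matches_bruteforce_on_random_sets(self, rng):
        for _ in range(200):
            n = rng.integers(1, 25)
            refs, alts = rng.random(n), rng.random(n)
            tau = rng.uniform(0.05, 0.95)
            scores = [WindowScore(i, r, a) for i, (r, a) in enumerate(zip(refs, alts))]
            brute_gain = sum(1 for r, a in zip(refs, alts) if r < tau and a >= tau)
            brute_loss = sum(1 for r, a in zip(refs, alts) if a < tau and r >= tau)
            assert ewn(scores, tau, "gain") == brute_gain
            assert ewn(scores, tau, "loss") == brute_loss


class TestClassify:
    def test_all_positive_with_ewn5_gained(self):
        scores = ws([(0.40, 0.70)] * 5 + [(0.40, 0.50)] * 16)
        assert classify(scores, 0.58).call == "gained"

    def test_17_of_21_consistency_fails(self):
        scores = ws([(0.40, 0.70)] * 6 + [(0.40, 0.50)] * 11 + [(0.50, 0.40)] * 4)
        call = classify(scores, 0.58)
        assert call.n_pos_delta == 17 and call.call == "none"

    def test_18_of_21_consistency_passes(self):
        scores = ws([(0.40, 0.70)] * 6 + [(0.40, 0.50)] * 12 + [(0.50, 0.40)] * 3)
        assert classify(scores, 0.58).call == "gained"

    def test_all_zero_deltas_none(self):
        scores = ws([(0.5, 0.5)] * 21)
        call = classify(scores, 0.58)
        assert call.call == "none" and call.mean_delta == 0.0

    def test_lost_symmetric(self):
        scores = ws([(0.70, 0.40)] * 5 + [(0.50, 0.40)] * 16)
        assert classify(scores, 0.58).call == "lost"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify([], 0.5)

    def test_agrees_with_bruteforce_reference(self, rng):
        def brute(refs, alts, tau, min_ewn=5, min_cons=0.85):
            n = len(refs)
            deltas = alts - refs
            e_gain = int(np.sum((refs < tau) & (alts >= tau)))
            e_loss = int(np.sum((alts < tau) & (refs >= tau)))
            if (deltas > 0).sum() > min_cons * n and e_gain >= min_ewn:
                return "gained"
            if (deltas < 0).sum() > min_cons * n and e_loss >= min_ewn:
                return "lost"
            return "none"

        for _ in range(10_000):
            n = rng.integers(1, 25)
            # quantized scores so boundary cases (delta == 0, score == tau) occur
            refs = rng.integers(0, 8, n) / 8
            alts = rng.integers(0, 8, n) / 8
            tau = rng.integers(1, 8) / 8
            scores = [WindowScore(i, r, a) for i, (r, a) in enumerate(zip(refs, alts))]
            assert classify(scores, tau).call == brute(refs, alts, tau)

    def test_gained_and_lost_mutually_exclusive(self, rng):
        for _ in range(2000):
            n = rng.integers(2, 25)
            refs, alts = rng.random(n), rng.random(n)
            tau = rng.uniform(0.05, 0.95)
            call = classify(
                [WindowScore(i, r, a) for i, (r, a) in enumerate(zip(refs, alts))],
                tau,
            )
            n_pos, n_neg = call.n_pos_delta, call.n_neg_delta
            assert not (n_pos > 0.85 * n and n_neg > 0.85 * n)


class TestWindowPairScores:
    def test_ref_mismatch_is_error(self, pwm_scorer):
        genome = {"chr1": "A" * 2000}
        v = VariantRecord("x", "chr1", 1000, "C", "T", 0.1, 0.2)
        with pytest.raises(ValueError, match="does not match genome base A"):
            ewn_scan.window_pair_scores(pwm_scorer, genome, v, stride=8, span=80)

    def test_degenerate_positions_sorted_and_complete(self, pwm_scorer):
        genome = {"chr1": "ACGT" * 1000}
        v = VariantRecord("x", "chr1", 2000, "A", "T", 0.1, 0.2)
        out = ewn_scan.window_pair_scores(pwm_scorer, genome, v, stride=8, span=80)
        assert len(out) == 21
        assert [w.center_offset for w in out] == list(range(-80, 81, 8))

    def test_motif_destroying_variant_negative_delta_everywhere(
        self, pwm_scorer, motifs
    ):
        from esnpscan import synthetic_data as sd

        genome = sd.simulate_genome(10_000, 0.41, 42)
        cons = motifs[0].consensus
        pos = 5000
        genome = genome[:pos] + cons + genome[pos + len(cons):]
        snp_pos = pos + 5
        v = VariantRecord("x", "chr1", snp_pos, genome[snp_pos], "C"
                          if genome[snp_pos] != "C" else "G", 0.1, 0.2)
        out = ewn_scan.window_pair_scores(
            pwm_scorer, {"chr1": genome}, v, stride=8, span=80
        )
        assert all(w.delta < 0 for w in out)


class TestScanCohort:
    def test_empty_variant_list(self, pwm_scorer):
        table = ewn_scan.scan_cohort(pwm_scorer, 0.5, {"chr1": "A" * 1000}, [])
        assert len(table) == 0

    def test_allele_swap_swaps_calls(self, pwm_scorer, motifs):
        from esnpscan import synthetic_data as sd

        genome = sd.simulate_genome(60_000, 0.41, 17)
        genome, variants, truth = sd.simulate_variants(genome, motifs, 30, seed=18)
        fwd = ewn_scan.scan_cohort(
            pwm_scorer, 0.5, {"chr1": genome}, variants, stride=8, span=80
        )
        # build the allele-swapped genome and the swapped variants
        g = list(genome)
        swapped = []
        for v in variants:
            g[v.pos] = v.alt
            swapped.append(
                VariantRecord(v.id, v.chrom, v.pos, v.alt, v.ref, v.af_ea, v.af_aa)
            )
        rev = ewn_scan.scan_cohort(
            pwm_scorer, 0.5, {"chr1": "".join(g)}, swapped, stride=8, span=80
        )
        flip = {"gained": "lost", "lost": "gained", "none": "none"}
        assert list(rev["call"]) == [flip[c] for c in fwd["call"]]
        np.testing.assert_array_equal(rev["ewn_gain"], fwd["ewn_loss"])
        np.testing.assert_array_equal(rev["ewn_loss"], fwd["ewn_gain"])

    def test_ref_mismatch_reported_not_dropped(self, pwm_scorer):
        genome = {"chr1": "A" * 2000}
        variants = [
            VariantRecord("bad", "chr1", 1000, "C", "T", 0.1, 0.2),
            VariantRecord("ok", "chr1", 1000, "A", "T", 0.1, 0.2),
        ]
        table = ewn_scan.scan_cohort(pwm_scorer, 0.5, genome, variants,
                                     stride=8, span=80)
        assert len(table) == 2
        assert table.loc[table["id"] == "bad", "status"].item().startswith("error")
        assert table.loc[table["id"] == "ok", "status"].item() == "ok"

    def test_edge_variant_unscannable(self, pwm_scorer):
        genome = {"chr1": "A" * 300}
        v = VariantRecord("edge", "chr1", 10, "A", "T", 0.1, 0.2)
        table = ewn_scan.scan_cohort(pwm_scorer, 0.5, genome, [v], stride=8, span=80)
        assert table["status"].item() == "unscannable"
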