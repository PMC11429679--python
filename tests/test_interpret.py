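"""Ranked partition, substitution splicing, IG, enrichment, G4 scanning."""

import re

import numpy as np
import pytest

from twinc.genome import onehot_from_string, string_from_onehot
from twinc.interpret import (
    g4_enrichment,
    integrated_gradients,
    merge_intervals,
    motif_enrichment,
    peaks_in_window,
    rank_and_partition,
    scan_g4,
    splice_intervals,
    substitute_peaks,
)
from twinc.model import TwinCConfig, build_model
from twinc.motifs import MotifOccurrence

from tests.conftest import store_from_seqs


def tiny_net(seed=0, head="classification"):
    return build_model(
        TwinCConfig(
            window_bp=100, latent_channels=6, latent_positions=5,
            encoder_channels=(4, 6), encoder_pools=(5, 4), encoder_kernel=3,
            decoder_channels=(6,), decoder_dilations=(1,), head=head,
        ),
        seed=seed,
    )


class TestRankedPartition:
    def test_floor_sizes_on_distinct_scores(self):
        pairs = [("c1", i, "c2", 0) for i in range(100)]
        scores = np.arange(100.0)
        part = rank_and_partition(pairs, scores)
        assert len(part.top) == 10 and len(part.next_) == 30
        assert part.top[0] == ("c1", 99, "c2", 0)  # highest score first

    def test_all_equal_scores_use_coordinate_tiebreak(self):
        pairs = [("c1", i * 100, "c2", 0) for i in range(20)]
        part = rank_and_partition(pairs, np.ones(20))
        assert part.top == [("c1", 0, "c2", 0), ("c1", 100, "c2", 0)]
        assert not set(part.top) & set(part.next_)

    def test_membership_matches_full_sort_oracle(self):
        rng = np.random.default_rng(0)
        pairs = [("c1", int(i), "c2", int(j)) for i, j in
                 rng.integers(0, 50, (60, 2))]
        scores = rng.random(60)
        part = rank_and_partition(pairs, scores)
        order = sorted(range(60), key=lambda k: (-scores[k], pairs[k]))
        assert part.top == [pairs[k] for k in order[:6]]
        assert part.next_ == [pairs[k] for k in order[6:24]]

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError):
            rank_and_partition([("c1", 0, "c2", 0)] * 5, np.ones(5))


class TestSplicing:
    def test_no_peaks_leaves_recipient_unchanged(self):
        a = onehot_from_string("ACGT" * 5)
        b = onehot_from_string("TTTT" * 5)
        assert np.array_equal(splice_intervals(a, b, []), b)

    def test_full_cover_makes_recipient_equal_donor(self):
        a = onehot_from_string("ACGT" * 5)
        b = onehot_from_string("TTTT" * 5)
        assert np.array_equal(splice_intervals(a, b, [(0, 20)]), a)

    def test_overlapping_intervals_merged(self):
        assert merge_intervals([(0, 5), (3, 8), (10, 12)]) == [(0, 8), (10, 12)]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = 50
        src = onehot_from_string("".join(rng.choice(list("ACGT"), L)))
        dst = onehot_from_string("".join(rng.choice(list("ACGT"), L)))
        ivs = [(int(s), int(s + rng.integers(1, 10)))
               for s in rng.integers(0, L - 10, 4)]
        got = splice_intervals(src, dst, ivs)
        covered = np.zeros(L, dtype=bool)
        for s, e in ivs:
            covered[s:e] = True
        for p in range(L):
            expect = src[p] if covered[p] else dst[p]
            assert np.array_equal(got[p], expect)

    def test_length_conserved(self):
        src = onehot_from_string("ACGT" * 10)
        dst = onehot_from_string("GGGG" * 10)
        out = splice_intervals(src, dst, [(5, 15)])
        assert out.shape == dst.shape


def test_read_bed_skips_headers_and_parses_intervals(tmp_path):
    from twinc.interpret import read_bed

    p = tmp_path / "peaks.bed"
    p.write_text("track name=peaks\nchr1\t10\t30\tpk1\nchr2\t0\t500\n\n")
    assert read_bed(p) == [("chr1", 10, 30), ("chr2", 0, 500)]


class TestSubstitutePeaks:
    def test_window_intersection_and_direction(self):
        store = store_from_seqs(c1="A" * 200, c2="C" * 200)
        peaks = [("c1", 10, 30), ("c1", 150, 170)]
        donor = ("c1", 0, "c1", 100)
        recipient = ("c2", 0, "c2", 100)
        outA, outB, n = substitute_peaks(donor, recipient, peaks, store, 100,
                                         "insert")
        sA = string_from_onehot(outA)
        assert sA[10:30] == "A" * 20 and sA[:10] == "C" * 10
        assert string_from_onehot(outB)[50:70] == "A" * 20  # peak at 150 in window@100
        assert n == 40

    def test_strip_direction_swaps_roles(self):
        store = store_from_seqs(c1="A" * 100, c2="C" * 100)
        outA, _, _ = substitute_peaks(
            ("c1", 0, "c1", 0), ("c2", 0, "c2", 0),
            [("c1", 0, 100)], store, 100, "strip",
        )
        assert string_from_onehot(outA) == "C" * 100


class TestIntegratedGradients:
    def test_zero_baseline_linear_model_recovers_w_times_x(self):
        """For F linear in the input, IG attributions are exactly w*x."""

        class LinearNet:
            config = type("C", (), {"window_bp": 8})

            def __init__(self, rng):
                self.wA = rng.normal(size=(8, 4)).astype(np.float32)
                self.wB = rng.normal(size=(8, 4)).astype(np.float32)

            def forward_pairs(self, xa, xb, train=False):
                self._shape = np.asarray(xa).shape
                return (
                    (np.asarray(xa) * self.wA).sum(axis=(1, 2))
                    + (np.asarray(xb) * self.wB).sum(axis=(1, 2))
                )

            def forward_pair(self, xa, xb):
                return float(self.forward_pairs(xa[None], xb[None])[0])

            def backward(self, dout):
                n = len(dout)
                ga = np.repeat(self.wA[None], n, axis=0) * dout[:, None, None]
                gb = np.repeat(self.wB[None], n, axis=0) * dout[:, None, None]
                return ga, gb

        rng = np.random.default_rng(0)
        net = LinearNet(rng)
        xa = np.eye(4, dtype=np.uint8)[rng.integers(0, 4, 8)]
        xb = np.eye(4, dtype=np.uint8)[rng.integers(0, 4, 8)]
        tA, tB, diag = integrated_gradients(net, xa, xb, steps=16)
        assert np.allclose(tA.scores, (xa * net.wA).sum(axis=1), atol=1e-5)
        assert np.allclose(tB.scores, (xb * net.wB).sum(axis=1), atol=1e-5)
        assert diag["completeness_residual"] < 1e-5

    def test_input_equal_baseline_gives_zero(self):
        net = tiny_net(seed=1)
        z = np.zeros((100, 4), dtype=np.float32)
        tA, tB, diag = integrated_gradients(net, z, z, steps=16)
        assert not tA.scores.any() and not tB.scores.any()

    @pytest.mark.parametrize("seed", range(5))
    def test_completeness_at_512_steps(self, seed):
        """Attributions sum to F(x) - F(baseline) within 0.1% (an absolute
        floor of 1e-6 covers float32 forward noise when the gap itself is
        vanishingly small)."""
        net = tiny_net(seed=seed)
        rng = np.random.default_rng(seed + 100)
        eye = np.eye(4, dtype=np.uint8)
        xa, xb = eye[rng.integers(0, 4, 100)], eye[rng.integers(0, 4, 100)]
        _, _, diag = integrated_gradients(net, xa, xb, steps=512)
        gap = abs(diag["f_input"] - diag["f_baseline"])
        assert diag["completeness_residual"] <= max(1e-3 * gap, 1e-6)

    def test_too_few_steps_rejected(self):
        net = tiny_net()
        z = np.zeros((100, 4))
        with pytest.raises(ValueError):
            integrated_gradients(net, z, z, steps=4)


def occ(motif_id, wid, offset, length=5):
    return MotifOccurrence(motif_id, wid, offset, "+", 10.0, 1e-6, length)


class TestMotifEnrichment:
    def test_real_above_decoy_gives_exact_minimal_p(self):
        """All real > all decoy with n=m=10: exact U p = 1/C(20,10)."""
        tracks = {0: np.concatenate([np.full(100, 5.0), np.full(100, 1.0)])}
        real = [occ("m", 0, i) for i in range(0, 50, 5)]          # high region
        decoy = [occ("m_decoy", 0, 100 + i) for i in range(0, 50, 5)]
        res = motif_enrichment(real, decoy, tracks, alpha=0.01)
        assert len(res) == 1
        from math import comb

        assert res[0].p_raw == pytest.approx(1.0 / comb(20, 10), rel=1e-6)
        assert res[0].enriched

    def test_below_floor_reported_untested(self):
        tracks = {0: np.ones(50)}
        res = motif_enrichment([occ("m", 0, 1)], [occ("m_decoy", 0, 2)],
                               tracks)
        assert len(res) == 1 and not res[0].tested and not res[0].enriched

    def test_null_calibration_rate_at_most_alpha(self):
        """With identical real/decoy distributions the BH-enriched fraction
        stays at or below alpha on average across seeds."""
        n_motifs, n_occ = 30, 12
        flags = 0
        trials = 30
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            tracks = {0: rng.normal(size=2000)}
            real, decoy = [], []
            for m in range(n_motifs):
                for k in range(n_occ):
                    real.append(occ(f"m{m}", 0, int(rng.integers(0, 1990))))
                    decoy.append(
                        occ(f"m{m}_decoy", 0, int(rng.integers(0, 1990)))
                    )
            res = motif_enrichment(real, decoy, tracks, alpha=0.01)
            flags += sum(r.enriched for r in res)
        assert flags / (trials * n_motifs) <= 0.01

    def test_adjusted_p_at_least_raw(self):
        rng = np.random.default_rng(1)
        tracks = {0: rng.normal(size=500)}
        real = [occ(f"m{m}", 0, int(rng.integers(0, 490)))
                for m in range(5) for _ in range(8)]
        decoy = [occ(f"m{m}_decoy", 0, int(rng.integers(0, 490)))
                 for m in range(5) for _ in range(8)]
        for r in motif_enrichment(real, decoy, tracks):
            if r.tested:
                assert r.p_adj >= r.p_raw


def oracle_g4_forward(seq):
    """Exhaustive-position scan: at each start, try to match the consensus
    greedily; count non-overlapping matches left to right."""
    pat = re.compile(r"G{3,}[ACGTN]{1,7}G{3,}[ACGTN]{1,7}G{3,}[ACGTN]{1,7}G{3,}")
    count = 0
    pos = 0
    while pos < len(seq):
        m = pat.match(seq, pos)
        if m:
            count += 1
            pos = m.end()
        else:
            pos += 1
    return count


class TestG4:
    def test_worked_pattern_single_forward_match(self):
        hits = scan_g4("GGGAGGGAGGGAGGG", strands="forward")
        assert len(hits) == 1
        assert hits[0] == (0, 15, "+")

    def test_no_match_in_ac_repeat(self):
        assert scan_g4("ACACAC" * 10) == []

    def test_reverse_strand_c_runs(self):
        hits = scan_g4("CCCTCCCTCCCTCCC", strands="both")
        assert [h[2] for h in hits] == ["-"]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_counts_match_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # G-rich alphabet so matches actually occur
        for _ in range(60):
            seq = "".join(rng.choice(list("GGGATC"), size=300))
            got = len(scan_g4(seq, strands="forward"))
            assert got == oracle_g4_forward(seq)

    def test_onehot_input_accepted(self):
        oh = onehot_from_string("GGGAGGGAGGGAGGG")
        assert len(scan_g4(oh, strands="forward")) == 1


class TestG4Enrichment:
    def test_strictly_higher_counts_give_auroc_one(self):
        scores = np.array([0.9] * 20 + [0.1] * 20)
        counts = np.array([5] * 20 + [1] * 20)
        rep = g4_enrichment(scores, counts)
        assert rep["auroc"] == 1.0 and rep["p_value"] < 1e-6

    def test_independent_counts_near_chance(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        counts = rng.poisson(3.0, 4000)
        rep = g4_enrichment(scores, counts)
        assert abs(rep["auroc"] - 0.5) < 0.05

    def test_half_threshold_sends_exact_to_no_contact(self):
        scores = np.array([0.5, 0.5, 0.9])
        counts = np.array([1, 2, 3])
        rep = g4_enrichment(scores, counts)
        assert rep["n_contact"] == 1 and rep["n_no_contact"] == 2

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            g4_enrichment(np.array([0.9, 0.8]), np.array([1, 2]))
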