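"""PWM scanning exactness, enrichment statistics, clustering and trees."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from regulome.motifs import (GRANULARITY, MotifClustering, PWM,
                             balanced_draw_enrichment,
                             cluster_peaks_by_motifs, fisher_group_enrichment,
                             gc_background, lognormal_enrichment_table,
                             lognormal_set_enrichment, positional_enrichment,
                             pwm_from_counts, pwm_similarity,
                             pwm_similarity_tree, qvalue_filter, scan_pwm,
                             score_distribution, sequence_affinity)
from regulome.simulate import random_pwm, simulate_sequences_with_motifs

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq):
    return seq.translate(COMPLEMENT)[::-1]


def enumeration_tail(pwm):
    """Exact tail p per discretized score by enumerating all 4^W words."""
    ints = np.rint(pwm.log_odds() / GRANULARITY).astype(np.int64)
    bg = pwm.background
    scores = {}
    for word in itertools.product(range(4), repeat=pwm.width):
        s = int(sum(ints[b, j] for j, b in enumerate(word)))
        p = math.prod(bg[b] for b in word)
        scores[s] = scores.get(s, 0.0) + p
    items = sorted(scores.items(), reverse=True)
    tail = {}
    acc = 0.0
    for s, p in items:
        acc += p
        tail[s] = acc
    return tail


class TestScanExactness:
    @pytest.mark.parametrize("width,gc", [(2, 0.5), (3, 0.5), (4, 0.62),
                                          (5, 0.38)])
    def test_dp_tail_equals_enumeration(self, width, gc):
        pwm = random_pwm(f"W{width}", width=width, seed=width,
                         background=gc_background(gc))
        dist = score_distribution(pwm)
        tail = enumeration_tail(pwm)
        for s, p in tail.items():
            assert dist.pvalue(s) == pytest.approx(p, rel=1e-9, abs=1e-300)

    def test_width_two_uniform_background_top_word(self):
        # p of the top-scoring dinucleotide = (# words scoring >= it) / 16
        counts = np.array([[8, 1], [1, 8], [1, 1], [1, 1]], dtype=float)
        pwm = pwm_from_counts("DI", counts, pseudocount=0.0)
        dist = score_distribution(pwm)
        ints = np.rint(pwm.log_odds() / GRANULARITY).astype(np.int64)
        top = int(ints.max(axis=0).sum())  # the word "AC"
        assert dist.pvalue(top) == pytest.approx(1 / 16)


class TestScanning:
    def test_flat_pwm_produces_no_hits(self, flat_pwm, rng):
        seq = "".join(rng.choice(list("ACGT"), 100))
        hits = scan_pwm({"s": seq}, flat_pwm, p_thresh=0.999)
        assert hits.empty  # score 0 everywhere -> p = 1, never < threshold

    def test_planted_site_found_at_offset(self, sharp_pwm):
        seq = "TTTTTTTTTT" + "ACGT" + "TTTTTTTTTT"
        hits = scan_pwm({"s": seq}, sharp_pwm, p_thresh=0.01)
        fwd = hits[hits.strand == "+"]
        assert 10 in fwd["start"].tolist()

    def test_reverse_complement_symmetry(self, sharp_pwm, rng):
        seq = "".join(rng.choice(list("ACGT"), 60))
        fwd = scan_pwm({"s": seq}, sharp_pwm, p_thresh=0.05)
        rev = scan_pwm({"s": revcomp(seq)}, sharp_pwm, p_thresh=0.05)
        L, W = len(seq), sharp_pwm.width
        mapped = sorted((L - W - h.start, {"+": "-", "-": "+"}[h.strand],
                         round(h.score, 6), round(h.p, 12))
                        for h in rev.itertuples())
        orig = sorted((h.start, h.strand, round(h.score, 6), round(h.p, 12))
                      for h in fwd.itertuples())
        assert mapped == orig

    def test_windows_with_n_skipped(self, sharp_pwm):
        hits = scan_pwm({"s": "ACGNACGT"}, sharp_pwm, p_thresh=1.0)
        assert (hits["start"] >= 4).all()

    def test_short_sequence_yields_no_hits(self, sharp_pwm):
        assert scan_pwm({"s": "ACG"}, sharp_pwm).empty


class TestQvalueFilter:
    def test_single_hit_keeps_own_p_as_q(self):
        hits = pd.DataFrame([("M", "s", 0, 4, "+", 1.0, 0.01)],
                            columns=["pwm_id", "seq_id", "start", "stop",
                                     "strand", "score", "p"])
        out = qvalue_filter(hits, q_max=0.05)
        assert out["q"].tolist() == [0.01]

    def test_equal_ps_all_kept_with_equal_q(self):
        hits = pd.DataFrame(
            [("M", f"s{i}", 0, 4, "+", 1.0, 0.04) for i in range(100)],
            columns=["pwm_id", "seq_id", "start", "stop", "strand", "score",
                     "p"])
        out = qvalue_filter(hits, q_max=0.05)
        assert len(out) == 100
        np.testing.assert_allclose(out["q"], 0.04)

    def test_p_one_dropped(self):
        hits = pd.DataFrame([("M", "s", 0, 4, "+", 0.0, 1.0)],
                            columns=["pwm_id", "seq_id", "start", "stop",
                                     "strand", "score", "p"])
        assert qvalue_filter(hits).empty


class TestLognormalEnrichment:
    def test_planted_motif_enriched_and_ranked_first(self, rng):
        pwm = random_pwm("PLANTED", width=8, sharpness=40, seed=11)
        fore, back, _ = simulate_sequences_with_motifs(
            60, 60, pwm, plant_rate_fore=0.9, plant_rate_back=0.02, seed=4)
        decoys = [random_pwm(f"D{i}", width=8, seed=100 + i)
                  for i in range(5)]
        table = lognormal_enrichment_table(fore, back, [pwm] + decoys)
        assert table.iloc[0]["pwm_id"] == "PLANTED"
        assert table.iloc[0]["p"] < 1e-3

    def test_background_vs_itself_p_near_half(self, rng):
        pwm = random_pwm("X", width=6, seed=2)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 80))
                for i in range(40)}
        res = lognormal_set_enrichment(seqs, seqs, pwm)
        assert 0.3 < res.p < 0.7

    def test_small_background_rejected(self, rng):
        pwm = random_pwm("X", width=6, seed=2)
        seqs = {f"s{i}": "ACGTACGTAC" for i in range(10)}
        with pytest.raises(ValueError):
            lognormal_set_enrichment(seqs, seqs, pwm)


class TestFisherGroupEnrichment:
    def test_perfect_separation_extreme_p(self):
        presence = pd.DataFrame(
            {"M1": [1] * 10 + [0] * 10, "M2": [1] * 20},
            index=[f"s{i}" for i in range(20)])
        labels = {f"s{i}": ("A" if i < 10 else "B") for i in range(20)}
        res = fisher_group_enrichment(presence, labels).set_index("motif")
        assert res.loc["M1", "p"] == pytest.approx(2 / 184756, rel=1e-9)
        assert res.loc["M2", "p"] == pytest.approx(1.0)

    def test_odds_ratio_direction(self):
        presence = pd.DataFrame({"M": [1] * 9 + [0] + [0] * 9 + [1]},
                                index=[f"s{i}" for i in range(20)])
        labels = {f"s{i}": ("A" if i < 10 else "B") for i in range(20)}
        res = fisher_group_enrichment(presence, labels)
        assert res["odds_ratio"].iloc[0] > 1


class TestBalancedDraw:
    @staticmethod
    def _fn_factory(always, per_draw_marker):
        def fn(seqs):
            out = set(always)
            if len(seqs) < 20:  # a subsample
                out |= set(per_draw_marker)
            return out
        return fn

    def test_intersection_rule(self):
        seqs = {f"s{i}": "ACGT" for i in range(30)}
        fn = self._fn_factory(always={"M_full_and_draws"},
                              per_draw_marker={"M_draw_only"})
        res = balanced_draw_enrichment(seqs, 10, fn, n_draws=3, seed=1)
        # significant in full set and in draws -> kept;
        # significant only in draws -> dropped (not in full result)
        assert res == ["M_full_and_draws"]

    def test_determinism(self, rng):
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 30))
                for i in range(25)}

        def fn(subset):
            return {sid for sid in subset if subset[sid].startswith("A")}

        a = balanced_draw_enrichment(seqs, 8, fn, n_draws=4, seed=9)
        b = balanced_draw_enrichment(seqs, 8, fn, n_draws=4, seed=9)
        assert a == b

    def test_oversized_draw_rejected(self):
        with pytest.raises(ValueError):
            balanced_draw_enrichment({"s": "ACGT"}, 5, lambda s: set())


class TestPeakClustering:
    def test_identical_rows_merged_first(self):
        mat = pd.DataFrame([[1, 0, 1], [1, 0, 1], [0, 1, 0]],
                           index=["p1", "p2", "p3"])
        res = cluster_peaks_by_motifs(mat)
        assert res.linkage[0, 2] == 0.0  # first merge at distance 0
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_leaf_order_is_permutation(self, rng):
        mat = pd.DataFrame(rng.integers(0, 2, size=(12, 5)))
        res = cluster_peaks_by_motifs(mat)
        assert sorted(res.leaf_order) == list(range(12))

    def test_two_block_structure_recovered(self, rng):
        block1 = np.tile([1, 1, 1, 0, 0, 0], (30, 1))
        block2 = np.tile([1, 1, 1, 1, 1, 1], (30, 1))
        noise = rng.random((60, 6)) < 0.05
        mat = pd.DataFrame(np.abs(np.vstack([block1, block2]) - noise))
        res = cluster_peaks_by_motifs(mat)
        labels = res.cut(2)
        truth = np.array([0] * 30 + [1] * 30)
        agree = max((labels - 1 == truth).mean(),
                    (2 - labels == truth).mean())
        assert agree >= 0.95

    def test_single_row_trivial(self):
        res = cluster_peaks_by_motifs(pd.DataFrame([[1, 0]]))
        assert list(res.leaf_order) == [0]


class TestPositionalEnrichment:
    HIT_COLS = ["pwm_id", "seq_id", "start", "stop", "strand", "score", "p"]

    def _hits(self, starts, width=4):
        return pd.DataFrame(
            [("M", f"s{i}", int(s), int(s) + width, "+", 1.0, 1e-4)
             for i, s in enumerate(starts)], columns=self.HIT_COLS)

    def test_all_central_hits_binomial_point_case(self):
        hits = self._hits([98, 99, 100])  # midpoints exactly central
        res = positional_enrichment(hits, seq_length=200, window=20,
                                    n_pwms_tested=1)
        assert res["p"].iloc[0] == pytest.approx((20 / 200) ** 3, rel=1e-9)

    def test_uniform_hits_not_enriched(self, rng):
        starts = rng.integers(0, 196, size=300)
        res = positional_enrichment(self._hits(starts), 200, 20, 1)
        assert res["p"].iloc[0] > 0.01

    def test_evalue_is_p_times_tests(self):
        hits = self._hits([98])
        res = positional_enrichment(hits, 200, 20, n_pwms_tested=50)
        assert res["evalue"].iloc[0] == pytest.approx(res["p"].iloc[0] * 50)

    def test_window_larger_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            positional_enrichment(self._hits([0]), 200, 300, 1)


class TestPwmSimilarity:
    def test_identical_pwms_similarity_one(self):
        p = random_pwm("A", width=6, seed=5)
        assert pwm_similarity(p, p) == pytest.approx(1.0)

    def test_reverse_complement_similarity_one(self):
        p = random_pwm("A", width=6, seed=5)
        assert pwm_similarity(p, p.reverse_complement()) == pytest.approx(1.0)

    def test_narrow_pwm_rejected(self):
        a = random_pwm("A", width=3, seed=1)
        b = random_pwm("B", width=6, seed=2)
        with pytest.raises(ValueError):
            pwm_similarity(a, b)

    def test_three_leaf_upgma_matches_hand_calculation(self):
        # Check the UPGMA arithmetic on the returned tree: the
        # two most similar PWMs merge first and the root height equals
        # the mean of their distances to the third.
        a = random_pwm("A", width=6, sharpness=30, seed=1)
        b = PWM(id="B", probs=np.clip(a.probs + 0.01, 1e-6, None)
                / (a.probs + 0.01).sum(axis=0))
        c = random_pwm("C", width=6, sharpness=30, seed=99)
        tree, sim = pwm_similarity_tree([a, b, c])
        d = 1 - sim
        tips = {t.name for t in tree.tips()}
        assert tips == {"A", "B", "C"}
        # A and B are near-identical -> they form the first cherry
        cherry = min(
            (n for n in tree.non_tips()),
            key=lambda n: len(list(n.tips())))
        assert {t.name for t in cherry.tips()} == {"A", "B"}
        # ultrametric root height = mean(d(A,C), d(B,C)) / 2
        root_height = max(tree.tip_tip_distances().data.max() / 2, 0)
        expected = (d.loc["A", "C"] + d.loc["B", "C"]) / 2 / 2
        assert root_height == pytest.approx(expected, rel=1e-6)

    def test_tree_is_ultrametric(self):
        pwms = [random_pwm(f"P{i}", width=6, seed=i) for i in range(5)]
        tree, _ = pwm_similarity_tree(pwms)
        # all tips equidistant from root in an ultrametric tree
        depths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
        vals = list(depths.values())
        assert max(vals) - min(vals) < 1e-9


def test_sequence_affinity_monotone_in_planted_content(sharp_pwm):
    with_motif = "TTTTT" + "ACGT" + "TTTTT"
    without = "TTTTTTTTTTTTTT"
    assert sequence_affinity(with_motif, sharp_pwm) > sequence_affinity(
        without, sharp_pwm)
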