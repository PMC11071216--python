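"""Target classification, fold-change shifts and bootstrap nulls."""

import numpy as np
import pandas as pd
import pytest

from regulome.targets import (classify_targets, concordance_bootstrap,
                              correlate_with_signatures, fc_shift_classes,
                              overlap_bootstrap, primary_targets,
                              variance_deciles)


def _cohort(rng, n=40):
    reg = rng.standard_normal(n)
    data = {
        "REG": reg,
        "ACT": 2 * reg + 0.01 * rng.standard_normal(n),
        "REP": -reg + 0.01 * rng.standard_normal(n),
        "NULL": rng.standard_normal(n),
        "FLAT": np.zeros(n),
    }
    return pd.DataFrame(data, index=[f"S{i}" for i in range(n)]).T


class TestClassifyTargets:
    def test_strong_positive_and_negative_targets(self, rng):
        expr = _cohort(rng)
        calls = classify_targets(["ACT", "REP", "NULL"], expr, "REG")
        by = calls.set_index("gene_id")["class"]
        assert by["ACT"] == "activated"
        assert by["REP"] == "repressed"
        assert by["NULL"] == "unclassified"

    def test_constant_target_flagged_not_tested(self, rng):
        calls = classify_targets(["FLAT"], _cohort(rng), "REG")
        rec = calls.iloc[0]
        assert rec["constant"] and rec["class"] == "unclassified"
        assert np.isnan(rec["p_adj"])

    def test_missing_regulator_rejected(self, rng):
        with pytest.raises(KeyError):
            classify_targets(["ACT"], _cohort(rng), "NOPE")

    def test_bonferroni_uses_number_tested(self, rng):
        expr = _cohort(rng)
        calls = classify_targets(["ACT", "REP", "NULL", "FLAT"], expr, "REG")
        tested = calls[~calls["constant"]]
        np.testing.assert_allclose(
            tested["p_adj"], np.minimum(1.0, tested["p"] * len(tested)))


class TestPrimaryTargets:
    DE = pd.DataFrame({
        "gene": ["up_sig", "down_sig", "up_ns", "outside"],
        "log2fc": [1.2, -0.8, 0.9, 2.0],
        "padj": [0.001, 0.01, 0.5, 0.001],
    })

    def test_sign_rule_and_chip_restriction(self):
        res = primary_targets({"up_sig", "down_sig", "up_ns"}, self.DE)
        assert res["repressed"] == {"up_sig"}
        assert res["activated"] == {"down_sig"}


class TestFcShift:
    def test_shift_classes_and_boundary(self):
        si = pd.DataFrame({"gene": ["a", "b", "c"],
                           "log2fc": [1.0, 0.25, -0.1],
                           "padj": [0.01] * 3})
        ct = pd.DataFrame({"gene": ["a", "b", "c"],
                           "log2fc": [0.5, 0.0, 0.25],
                           "padj": [0.5] * 3})
        res = fc_shift_classes(si, ct, ["a", "b", "c"]).set_index("gene_id")
        assert res.loc["a", "class"] == "iDEG"      # shift 0.5
        assert res.loc["b", "class"] == "independent"  # boundary 0.25
        assert res.loc["c", "class"] == "dDEG"      # shift -0.35

    def test_missing_genes_dropped_and_counted(self):
        si = pd.DataFrame({"gene": ["a"], "log2fc": [1.0], "padj": [0.01]})
        ct = pd.DataFrame({"gene": ["a", "b"], "log2fc": [0.0, 0.0],
                           "padj": [0.5, 0.5]})
        res = fc_shift_classes(si, ct, ["a", "b"])
        assert res.attrs["dropped"] == 1
        assert res["gene_id"].tolist() == ["a"]

    def test_partition_of_restricted_genes(self, rng):
        genes = [f"g{i}" for i in range(200)]
        si = pd.DataFrame({"gene": genes,
                           "log2fc": rng.standard_normal(200),
                           "padj": rng.uniform(0, 1, 200)})
        ct = pd.DataFrame({"gene": genes,
                           "log2fc": rng.standard_normal(200),
                           "padj": rng.uniform(0, 1, 200)})
        res = fc_shift_classes(si, ct, genes)
        assert len(res) == 200
        assert set(res["class"]) <= {"iDEG", "dDEG", "independent"}


class TestBootstraps:
    def test_concordance_perfect_match_minimal_p(self):
        signs = {f"g{i}": "up" for i in range(20)}
        universe = dict(signs, **{f"h{i}": "down" for i in range(80)})
        res = concordance_bootstrap(signs, universe, n_iter=200, seed=3)
        assert res.observed == 1.0
        assert res.p_empirical <= (1 + 5) / 201  # ties only at concordance 1

    def test_concordance_null_mean_near_half(self, rng):
        universe = {f"g{i}": ("up" if i % 2 else "down") for i in range(400)}
        sub = {f"g{i}": "up" for i in range(0, 400, 8)}
        res = concordance_bootstrap(sub, universe, n_iter=2000, seed=1)
        mc_se = np.std(res.null_samples) / np.sqrt(res.n_iter)
        assert abs(np.mean(res.null_samples) - 0.5) < 3 * mc_se

    def test_fixed_seed_reproduces_null_samples(self):
        universe = {f"g{i}": ("up" if i % 3 else "down") for i in range(100)}
        sub = {f"g{i}": "down" for i in range(10)}
        a = concordance_bootstrap(sub, universe, n_iter=100, seed=7)
        b = concordance_bootstrap(sub, universe, n_iter=100, seed=7)
        np.testing.assert_array_equal(a.null_samples, b.null_samples)
        assert a.p_empirical == b.p_empirical

    def test_overlap_null_mean_matches_hypergeometric(self):
        universe = [f"g{i}" for i in range(500)]
        query = universe[:100]
        ref = universe[50:150]
        res = overlap_bootstrap(query, ref, universe, n_iter=3000, seed=2)
        expected = len(query) * len(ref) / len(universe)  # 20
        mc_se = np.std(res.null_samples) / np.sqrt(res.n_iter)
        assert abs(np.mean(res.null_samples) - expected) < 3 * mc_se

    def test_overlap_reference_subset_of_query_is_extreme(self):
        universe = [f"g{i}" for i in range(200)]
        query = universe[:150]
        ref = universe[:30]
        res = overlap_bootstrap(query, ref, universe, n_iter=500, seed=5)
        assert res.observed == 30
        assert res.p_empirical < 0.05

    def test_disjoint_sets_large_universe_p_near_one(self):
        universe = [f"g{i}" for i in range(1000)]
        res = overlap_bootstrap(universe[:20], universe[500:520], universe,
                                n_iter=300, seed=9)
        assert res.observed == 0
        assert res.p_empirical > 0.5

    def test_empirical_p_never_zero(self):
        universe = [f"g{i}" for i in range(50)]
        res = overlap_bootstrap(universe[:10], universe[:10], universe,
                                n_iter=100, seed=1)
        assert 0 < res.p_empirical <= 1


class TestVarianceDeciles:
    def test_constant_genes_all_zero(self):
        expr = pd.DataFrame(np.ones((5, 4)),
                            columns=["a", "b", "c", "d"])
        res = variance_deciles(expr, {c: "g1" for c in expr.columns})
        assert (res["g1"] == 0).all()

    def test_interpolated_median_of_known_variances(self, rng):
        # 20 genes whose per-gene variances are exactly 1..20
        cols = ["s1", "s2"]
        rows = []
        for v in range(1, 21):
            half = np.sqrt(v / 2.0)
            rows.append([-half, half])  # sample variance = v (ddof=1)
        expr = pd.DataFrame(rows, columns=cols)
        res = variance_deciles(expr, {"s1": "g", "s2": "g"})
        assert res.loc["decile_5", "g"] == pytest.approx(10.5)

    def test_deciles_monotone(self, rng):
        expr = pd.DataFrame(rng.standard_normal((50, 6)),
                            columns=[f"s{i}" for i in range(6)])
        res = variance_deciles(expr, {f"s{i}": "g" for i in range(6)})
        assert (np.diff(res["g"]) >= 0).all()

    def test_single_sample_group_rejected(self):
        expr = pd.DataFrame(np.ones((3, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            variance_deciles(expr, {"a": "g1", "b": "g2"})


class TestSignatureCorrelation:
    def test_gene_equal_to_signature_has_r_one(self, rng):
        samples = [f"S{i}" for i in range(30)]
        sig = pd.DataFrame({"state": rng.standard_normal(30)}, index=samples)
        expr = pd.DataFrame([sig["state"].to_numpy()], index=["G1"],
                            columns=samples)
        res = correlate_with_signatures(expr, sig)
        assert res["r"].iloc[0] == pytest.approx(1.0)
        assert res["significant"].iloc[0]

    def test_independent_noise_rarely_significant(self, rng):
        samples = [f"S{i}" for i in range(30)]
        sig = pd.DataFrame(rng.standard_normal((30, 4)),
                           index=samples,
                           columns=[f"sig{i}" for i in range(4)])
        expr = pd.DataFrame(rng.standard_normal((25, 30)),
                            index=[f"G{i}" for i in range(25)],
                            columns=samples)
        res = correlate_with_signatures(expr, sig)
        assert res["r"].abs().max() <= 1.0
        assert res["significant"].mean() < 0.05

    def test_no_shared_samples_rejected(self, rng):
        sig = pd.DataFrame({"s": [1.0, 2.0]}, index=["X1", "X2"])
        expr = pd.DataFrame([[1.0, 2.0]], index=["G"], columns=["Y1", "Y2"])
        with pytest.raises(ValueError):
            correlate_with_signatures(expr, sig)
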