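"""Differential expression, co-expression, gene-set score, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

import brainmet as bm
from brainmet.expression import median_of_ratios_size_factors


def matrix_from_rows(rows, scale="count", prefix="S"):
    genes = list(rows)
    n = len(next(iter(rows.values())))
    df = pd.DataFrame(rows, index=[f"{prefix}{i}" for i in range(n)]).T
    return bm.ExpressionMatrix(df.astype(float), scale)


class TestDifferentialExpression:
    def _two_class_labels(self, n_pos, n_neg):
        return pd.Series(["A"] * n_pos + ["B"] * n_neg,
                         index=[f"S{i}" for i in range(n_pos + n_neg)])

    def test_identical_values_not_deg(self):
        # constant filler genes pin the size factors at 1
        rows = {"gene": [5, 5, 5, 5, 5, 5, 5, 5]}
        rows.update({f"bg{i}": [10 + i] * 8 for i in range(20)})
        expr = matrix_from_rows(rows)
        de = bm.differential_expression(expr, self._two_class_labels(4, 4),
                                        positive_class="A")
        assert de.loc["gene", "log2FC"] == pytest.approx(0.0)
        assert not de.loc["gene", "is_deg"]

    def test_fold_change_threshold_is_inclusive(self):
        """A gene at exactly log2FC = 1 with small p is selected."""
        rows = {"gene": [2, 4, 2, 4, 2, 4, 0, 2, 0, 2, 0, 2]}
        rows.update({f"bg{i}": [10 + i] * 12 for i in range(30)})
        expr = matrix_from_rows(rows)
        labels = self._two_class_labels(6, 6)
        de = bm.differential_expression(expr, labels, positive_class="A")
        # normalized class means 3 and 1 -> log2((3+1)/(1+1)) = 1 exactly
        assert de.loc["gene", "log2FC"] == pytest.approx(1.0)
        assert de.loc["gene", "p_value"] < 0.05
        assert bool(de.loc["gene", "is_deg"])
        assert de.loc["gene", "direction"] == "up"

    def test_label_swap_negates_log2fc(self, small_cohort):
        _, counts, _, labels, _ = small_cohort
        a = bm.differential_expression(counts, labels["class"], positive_class="BMP")
        b = bm.differential_expression(counts, labels["class"], positive_class="NBMP")
        np.testing.assert_allclose(a["log2FC"].values, -b["log2FC"].values, atol=1e-12)

    def test_requires_count_scale(self, small_cohort):
        _, _, tpm, labels, _ = small_cohort
        with pytest.raises(ValueError, match="count"):
            bm.differential_expression(tpm, labels["class"])

    def test_requires_two_samples_per_class(self):
        rows = {"g": [1, 2, 3]}
        expr = matrix_from_rows(rows)
        labels = pd.Series(["A", "B", "B"], index=expr.sample_ids)
        with pytest.raises(ValueError, match="at least 2"):
            bm.differential_expression(expr, labels)

    def test_type_i_error_near_nominal(self):
        """Null cohorts (no effect): ~5% of genes reach p < 0.05."""
        fracs = []
        for seed in range(3):
            cfg = bm.CohortConfig(n_pos=30, n_neg=30, n_genes=800, n_tm_de=10,
                                  n_enzymes=10, n_enzyme_signal=2,
                                  effect_log2fc=0.0, seed=seed)
            counts, _, labels, _ = bm.generate_cohort(cfg)
            de = bm.differential_expression(counts, labels["class"],
                                            positive_class="BMP")
            fracs.append((de["p_value"] < 0.05).mean())
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_size_factors_recover_library_scaling(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(4, 1, 300)
        scale = np.array([1.0, 2.0, 0.5, 1.5])
        df = pd.DataFrame(np.outer(base, scale),
                          index=[f"g{i}" for i in range(300)],
                          columns=list("abcd"))
        sf = median_of_ratios_size_factors(df)
        np.testing.assert_allclose(sf.values / sf.values[0], scale, rtol=1e-9)


class TestCoexpression:
    def _noise_matrix(self, n_genes, n_samples, seed=0):
        # light-tailed by design: Pearson is outlier-sensitive on
        # heavy-tailed marginals (see docs/methods.md)
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.uniform(1, 100, (n_genes, n_samples)),
                          index=[f"g{i}" for i in range(n_genes)],
                          columns=[f"s{j}" for j in range(n_samples)])
        return bm.ExpressionMatrix(df, "tpm")

    def test_identical_profile_retained_with_unit_pcc(self):
        expr = self._noise_matrix(5, 30)
        expr.data.loc["g1"] = expr.data.loc["g0"].values
        pairs = bm.pearson_coexpression(expr, ["g0"], ["g1"])
        assert len(pairs) == 1
        assert pairs.iloc[0]["pcc"] == pytest.approx(1.0)

    def test_perfect_anticorrelation_excluded(self):
        """The screen is one-sided: only positive co-expression counts."""
        expr = self._noise_matrix(5, 30)
        prof = expr.data.loc["g0"]
        expr.data.loc["g1"] = (2 * prof.mean() - prof).values
        pairs = bm.pearson_coexpression(expr, ["g0"], ["g1"])
        assert pairs.empty

    def test_null_noise_retains_no_pairs(self):
        """Independent noise, 50 samples, 200 candidates: ~0 pairs pass
        PCC > 0.6 with p < 1e-4."""
        expr = self._noise_matrix(201, 50, seed=3)
        pairs = bm.pearson_coexpression(expr, ["g0"], [f"g{i}" for i in range(1, 201)])
        assert len(pairs) == 0

    def test_affine_transform_invariance(self):
        expr = self._noise_matrix(4, 25, seed=5)
        before = bm.pearson_coexpression(expr, ["g0"], ["g1", "g2", "g3"],
                                         pcc_threshold=-2, p_threshold=2)
        expr.data.loc["g0"] = 3.0 * expr.data.loc["g0"].values + 7.0
        after = bm.pearson_coexpression(expr, ["g0"], ["g1", "g2", "g3"],
                                        pcc_threshold=-2, p_threshold=2)
        np.testing.assert_allclose(before["pcc"].values, after["pcc"].values,
                                   atol=1e-12)

    def test_constant_gene_skipped_with_warning(self):
        expr = self._noise_matrix(3, 20)
        expr.data.loc["g1"] = 4.0
        with pytest.warns(UserWarning, match="constant"):
            pairs = bm.pearson_coexpression(expr, ["g0"], ["g1", "g2"])
        assert "g1" not in pairs.get("candidate", pd.Series(dtype=object)).tolist()

    def test_unknown_gene_rejected(self):
        expr = self._noise_matrix(3, 20)
        with pytest.raises(KeyError):
            bm.pearson_coexpression(expr, ["missing"], ["g0"])


class TestGeneSetScore:
    def test_identical_samples_score_equally(self):
        df = pd.DataFrame({"s1": [1.0, 5.0, 2.0, 8.0], "s2": [1.0, 5.0, 2.0, 8.0]},
                          index=list("abcd"))
        expr = bm.ExpressionMatrix(df, "tpm")
        scores = bm.gene_set_score(expr, bm.GeneSet("set", frozenset("ab")))
        assert scores["s1"] == pytest.approx(scores["s2"])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.lognormal(2, 1, (50, 6)),
                          index=[f"g{i}" for i in range(50)],
                          columns=[f"s{j}" for j in range(6)])
        gs = bm.GeneSet("set", frozenset(f"g{i}" for i in range(10)))
        a = bm.gene_set_score(bm.ExpressionMatrix(df, "tpm"), gs)
        b = bm.gene_set_score(bm.ExpressionMatrix(np.log1p(df) ** 2, "tpm"), gs)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_higher_member_ranks_give_higher_score(self):
        df = pd.DataFrame({"low": [10, 1, 1, 9, 8, 7], "high": [1, 9, 10, 1, 2, 3]},
                          index=[f"g{i}" for i in range(6)], dtype=float)
        expr = bm.ExpressionMatrix(df, "tpm")
        gs = bm.GeneSet("set", frozenset(["g1", "g2"]))
        scores = bm.gene_set_score(expr, gs)
        assert scores["high"] > scores["low"]

    def test_whole_universe_set_is_constant(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.lognormal(2, 1, (30, 5)),
                          index=[f"g{i}" for i in range(30)],
                          columns=[f"s{j}" for j in range(5)])
        expr = bm.ExpressionMatrix(df, "tpm")
        gs = bm.GeneSet("all", frozenset(df.index))
        scores = bm.gene_set_score(expr, gs)
        np.testing.assert_allclose(scores.values, scores.values[0], atol=1e-12)

    def test_planted_upregulated_set_separates_classes(self, default_cohort):
        """The planted enzyme set scores higher in the positive class."""
        from scipy import stats

        _, _, tpm, labels, truth = default_cohort
        gs = bm.GeneSet("planted", frozenset(truth.informative_enzyme_ids))
        scores = bm.gene_set_score(tpm, gs)
        pos = scores[labels["class"] == "BMP"]
        neg = scores[labels["class"] == "NBMP"]
        t, p = stats.ttest_ind(pos, neg, equal_var=False)
        assert pos.mean() > neg.mean()
        assert p < 0.05

    def test_agrees_with_independent_ssgsea_implementation(self):
        """Sample ordering matches an external single-sample enrichment
        implementation on a planted fixture."""
        gseapy = pytest.importorskip("gseapy")
        from scipy import stats

        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(60)]
        df = pd.DataFrame(rng.lognormal(2, 1, (60, 8)), index=genes,
                          columns=[f"s{j}" for j in range(8)])
        members = genes[:8]
        df.loc[members, [f"s{j}" for j in range(4)]] *= 6
        mine = bm.gene_set_score(bm.ExpressionMatrix(df, "tpm"),
                                 bm.GeneSet("set", frozenset(members)))
        res = gseapy.ssgsea(data=df, gene_sets={"set": members}, outdir=None,
                            sample_norm_method="rank", min_size=2,
                            no_plot=True)
        theirs = res.res2d.set_index("Name")["ES"].astype(float).reindex(mine.index)
        rho, _ = stats.spearmanr(mine.values, theirs.values)
        assert rho > 0.9

    def test_empty_intersection_rejected(self):
        df = pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="no genes"):
            bm.gene_set_score(bm.ExpressionMatrix(df, "tpm"),
                              bm.GeneSet("s", frozenset(["zz"])))


class TestEnrichment:
    def test_matches_closed_form_hypergeometric_tail(self):
        """Full-membership query in a small universe equals the exact tail."""
        universe = [f"g{i}" for i in range(20)]
        gs = bm.GeneSet("set", frozenset(universe[:5]))
        query = universe[:5]
        res = bm.enrichment_test(query, [gs], universe)
        M, K, N, k = 20, 5, 5, 5
        tail = sum(
            math.comb(K, x) * math.comb(M - K, N - x) / math.comb(M, N)
            for x in range(k, min(K, N) + 1)
        )
        assert res.iloc[0]["p_value"] == pytest.approx(tail)
        assert res.iloc[0]["enriched"] == (tail < 1e-4)

    def test_disjoint_query_has_p_one(self):
        universe = [f"g{i}" for i in range(30)]
        gs = bm.GeneSet("set", frozenset(universe[:10]))
        res = bm.enrichment_test(universe[10:15], [gs], universe)
        assert res.iloc[0]["p_value"] == pytest.approx(1.0)
        assert not res.iloc[0]["enriched"]

    def test_random_overlap_p_is_roughly_uniform(self):
        rng = np.random.default_rng(9)
        universe = [f"g{i}" for i in range(200)]
        gs = bm.GeneSet("set", frozenset(universe[:40]))
        ps = []
        for _ in range(200):
            query = list(rng.choice(universe, size=30, replace=False))
            ps.append(bm.enrichment_test(query, [gs], universe).iloc[0]["p_value"])
        # discrete p-values are conservative but should not pile up near 0
        assert np.mean(ps) > 0.35
        assert min(ps) > 1e-6

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            bm.enrichment_test(["x"], [bm.GeneSet("s", frozenset(["a"]))], ["a", "b"])


class TestGmtRoundtrip:
    def test_write_then_read(self, tmp_path):
        sets = [bm.GeneSet("one", frozenset(["a", "b"])),
                bm.GeneSet("two", frozenset(["c"]))]
        p = tmp_path / "sets.gmt"
        bm.expression.write_gmt(sets, p)
        loaded = bm.expression.read_gmt(p)
        assert {s.name: s.members for s in loaded} == {s.name: s.members for s in sets}
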