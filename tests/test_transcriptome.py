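import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardioage import transcriptome as tx
from cardioage.synthetic import CountSimConfig, PlantedSet, gen_count_matrix


def toy_matrix(counts, genotypes=None, ages=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"g{i}" for i in range(counts.shape[0])]
    counts.columns = [f"s{j}" for j in range(counts.shape[1])]
    n = counts.shape[1]
    samples = pd.DataFrame({
        "genotype": genotypes or ["FVB"] * n,
        "age": ages or [4] * n,
    }, index=counts.columns)
    return tx.CountMatrix(counts=counts, samples=samples)


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        cm = toy_matrix(np.tile([[10], [200], [5], [80], [40], [100]], (1, 3)))
        f = tx.normalize_counts(cm).factors
        np.testing.assert_allclose(f, 1.0, atol=1e-12)

    def test_pure_library_scaling_absorbed_by_lib_size(self):
        col = np.array([10, 200, 5, 80, 40, 100])
        cm = toy_matrix(np.column_stack([col, 2 * col]))
        f = tx.normalize_counts(cm).factors
        np.testing.assert_allclose(f, 1.0, atol=1e-12)

    def test_factors_have_unit_geometric_mean(self, rng):
        x = rng.negative_binomial(5, 0.01, size=(300, 5))
        x[:60, 1] *= 4
        f = tx.normalize_counts(toy_matrix(x)).factors
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)

    def test_toy_matrix_matches_hand_computation(self):
        # 6 genes, 2 samples; reference is sample 0 (upper quartiles tie).
        # With 6 genes the 30%/5% trims each remove the lowest/highest
        # ranked M and A values, leaving the middle genes: replicate the
        # trimmed weighted M-mean directly.
        x = np.array([[100, 150], [200, 440], [300, 620], [400, 850],
                      [500, 1100], [600, 1550]], dtype=float)
        cm = toy_matrix(x.astype(int))
        f = tx.normalize_counts(cm).factors
        na, nb = x[:, 0].sum(), x[:, 1].sum()
        m = np.log2((x[:, 1] / nb) / (x[:, 0] / na))
        a = 0.5 * np.log2((x[:, 1] / nb) * (x[:, 0] / na))
        w = 1.0 / ((nb - x[:, 1]) / (nb * x[:, 1]) + (na - x[:, 0]) / (na * x[:, 0]))
        n = len(m)
        lo_m, hi_m = math.floor(n * 0.3) + 1, n - math.floor(n * 0.3)
        lo_a, hi_a = math.floor(n * 0.05) + 1, n - math.floor(n * 0.05)
        rm = pd.Series(m).rank().to_numpy()
        ra = pd.Series(a).rank().to_numpy()
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        expected = 2.0 ** (np.sum(m[keep] * w[keep]) / np.sum(w[keep]))
        expected_pair = np.array([1.0, expected])
        expected_pair /= np.exp(np.mean(np.log(expected_pair)))
        np.testing.assert_allclose(f, expected_pair, rtol=1e-9)

    def test_matches_edger_oracle(self, tmp_path, rng):
        x = rng.negative_binomial(5, 0.01, size=(200, 4))
        x[:50, 2] *= 3
        path = tmp_path / "m.tsv"
        pd.DataFrame(x).to_csv(path, sep="\t", index=False, header=False)
        out = subprocess.run(
            ["Rscript", "-e",
             f'x <- as.matrix(read.table("{path}")); '
             'suppressMessages(library(edgeR)); '
             'cat(sprintf("%.10f", calcNormFactors(x, method="TMM")), sep="\\n")'],
            capture_output=True, text=True, check=True)
        edger = np.array([float(v) for v in out.stdout.split()])
        mine = tx.normalize_counts(toy_matrix(x)).factors.to_numpy()
        np.testing.assert_allclose(mine, edger, rtol=1e-6)

    def test_zero_library_rejected(self):
        cm = toy_matrix(np.array([[1, 0], [2, 0], [3, 0]]))
        with pytest.raises(ValueError, match="zero library"):
            tx.normalize_counts(cm)


class TestFilter:
    def _norm(self, cpm, groups):
        cpm = pd.DataFrame(cpm)
        cpm.index = [f"g{i}" for i in range(cpm.shape[0])]
        cpm.columns = [f"s{j}" for j in range(cpm.shape[1])]
        samples = pd.DataFrame({"genotype": ["FVB"] * cpm.shape[1], "age": groups},
                               index=cpm.columns)
        return tx.NormalizationResult(
            factors=pd.Series(1.0, index=cpm.columns),
            lib_sizes=pd.Series(1e6, index=cpm.columns),
            cpm=cpm, samples=samples)

    def test_gene_passing_in_four_samples_retained(self):
        cpm = np.zeros((2, 5))
        cpm[0, :4] = 0.6            # cpm > 0.5 in 4 samples of one group
        norm = self._norm(cpm, [4] * 5)
        kept = tx.filter_genes(norm)
        assert "g0" in kept and "g1" not in kept

    def test_exactly_three_samples_not_enough(self):
        cpm = np.zeros((1, 5))
        cpm[0, :3] = 10.0
        norm = self._norm(cpm, [4] * 5)
        assert len(tx.filter_genes(norm)) == 0

    def test_threshold_is_strict(self):
        cpm = np.full((1, 5), 0.5)  # exactly at the cut: not > 0.5
        norm = self._norm(cpm, [4] * 5)
        assert len(tx.filter_genes(norm)) == 0

    def test_matches_bruteforce_rule_oracle(self, rng):
        cpm = rng.gamma(1.0, 1.0, size=(20, 10))
        ages = [4] * 5 + [14] * 5
        norm = self._norm(cpm, ages)
        kept = set(tx.filter_genes(norm))
        for i in range(20):
            expected = any(
                sum(cpm[i, j] > 0.5 for j in range(10) if ages[j] == a) > 3
                for a in (4, 14))
            assert (f"g{i}" in kept) == expected


class TestDifferentialExpression:
    def _norm_from_counts(self, counts, ages):
        cm = toy_matrix(counts, ages=ages)
        return tx.normalize_counts(cm), cm

    def test_threshold_is_strict_on_logfc(self):
        table = pd.DataFrame({"logFC": [1.0], "adj_p": [0.01]})
        is_deg = (table["logFC"].abs() > tx.LOGFC_THRESHOLD) & \
                 (table["adj_p"] < tx.ADJP_THRESHOLD)
        # the production rule must agree with the strict reading
        assert not is_deg[0]
        cfg = CountSimConfig(n_genes=300, groups=(("FVB", 4, 4), ("FVB", 14, 4)),
                             planted_sets=(), seed=0)
        cm, _ = gen_count_matrix(cfg)
        norm = tx.normalize_counts(cm)
        out = tx.differential_expression(norm, cm.samples_of("FVB", 14),
                                         cm.samples_of("FVB", 4))
        recomputed = (out["logFC"].abs() > 1.0) & (out["adj_p"] < 0.05)
        assert (out["is_deg"] == recomputed).all()

    def test_null_data_rarely_flagged(self):
        cfg = CountSimConfig(n_genes=2000, groups=(("FVB", 4, 6), ("FVB", 14, 6)),
                             planted_sets=(), seed=1)
        cm, _ = gen_count_matrix(cfg)
        norm = tx.normalize_counts(cm)
        kept = tx.filter_genes(norm)
        out = tx.differential_expression(norm, cm.samples_of("FVB", 14),
                                         cm.samples_of("FVB", 4), genes=kept)
        assert out["is_deg"].mean() < 0.05

    def test_planted_logfc3_recovered_at_95_percent(self):
        planted = (PlantedSet("up", 40, 3.0, (("FVB", 14),)),)
        cfg = CountSimConfig(n_genes=2000, nb_dispersion=0.05,
                             groups=(("FVB", 4, 6), ("FVB", 14, 6)),
                             planted_sets=planted, seed=2)
        cm, truth = gen_count_matrix(cfg)
        norm = tx.normalize_counts(cm)
        kept = tx.filter_genes(norm)
        out = tx.differential_expression(norm, cm.samples_of("FVB", 14),
                                         cm.samples_of("FVB", 4), genes=kept)
        degs = tx.deg_set(out)
        planted_genes = set(truth.params["memberships"]["up"])
        assert len(degs & planted_genes) / len(planted_genes) >= 0.95

    def test_zero_variance_gene_flagged_not_crashed(self):
        counts = np.abs(np.arange(60).reshape(10, 6)) + 5
        counts[0] = 50                      # identical in every sample
        norm, cm = self._norm_from_counts(counts, [4, 4, 4, 14, 14, 14])
        out = tx.differential_expression(norm, cm.samples_of("FVB", 14),
                                         cm.samples_of("FVB", 4))
        assert np.isfinite(out["p"]).all()

    def test_requires_two_samples_per_group(self):
        norm, cm = self._norm_from_counts(np.ones((5, 4), dtype=int) * 10,
                                          [4, 4, 4, 14])
        with pytest.raises(ValueError):
            tx.differential_expression(norm, cm.samples_of("FVB", 14),
                                       cm.samples_of("FVB", 4))


class TestClassification:
    def test_fig8_arithmetic(self):
        aged = {f"a{i}" for i in range(454)}
        shared = {f"s{i}" for i in range(481)}
        deg = {14: aged | shared, 12: set(shared) & {f"s{i}" for i in range(200)},
               10: {f"s{i}" for i in range(150, 481)}, 8: set(), 6: {"s0"}}
        part = tx.classify_ageing_genes(deg)
        assert len(part.cardiac_ageing) == 935
        assert len(part.aged_only) == 454
        assert len(part.ageing) == 481

    def test_empty_oldest_set(self):
        part = tx.classify_ageing_genes({a: set() for a in (6, 8, 10, 12, 14)})
        assert not part.aged_only and not part.ageing and not part.cardiac_ageing

    def test_oldest_subset_of_younger(self):
        deg14 = {"x", "y"}
        part = tx.classify_ageing_genes({6: deg14 | {"z"}, 8: set(), 10: set(),
                                         12: set(), 14: deg14})
        assert part.aged_only == frozenset()
        assert part.ageing == deg14

    def test_missing_comparison_rejected(self):
        with pytest.raises(KeyError):
            tx.classify_ageing_genes({14: set(), 12: set()})

    def test_partition_invariants_enforced(self):
        with pytest.raises(ValueError):
            tx.AgeingPartition(aged_only={"a"}, ageing={"a"})

    def test_contribution_fraction_counting(self):
        part = tx.AgeingPartition(aged_only={f"a{i}" for i in range(10)},
                                  ageing={f"b{i}" for i in range(25)})
        hf = {f"a{i}" for i in range(10)} | {f"b{i}" for i in range(25)} | \
             {f"c{i}" for i in range(65)}
        assert tx.contribution_fraction(part, hf) == pytest.approx(35.0)
        assert tx.contribution_fraction(part, {"zz"}) == pytest.approx(0.0)
        assert tx.contribution_fraction(part, {"a1", "b2"}) == pytest.approx(100.0)

    def test_contribution_invariant_to_unrelated_genes(self):
        part = tx.AgeingPartition(aged_only={"a"}, ageing={"b"})
        hf = {"a", "x"}
        base = tx.contribution_fraction(part, hf)
        part2 = tx.AgeingPartition(aged_only={"a", "q"}, ageing={"b", "r"})
        assert tx.contribution_fraction(part2, hf) == pytest.approx(base)

    def test_empty_hf_list_flagged(self):
        part = tx.AgeingPartition(aged_only={"a"}, ageing=set())
        with pytest.warns(RuntimeWarning):
            assert np.isnan(tx.contribution_fraction(part, set()))


class TestORA:
    def test_zero_overlap_gives_p_one(self):
        bg = {f"g{i}" for i in range(20)}
        res = tx.overrepresentation({"g0", "g1"}, bg, {"t": {"g10", "g11"}})
        assert res.loc["t", "p"] == pytest.approx(1.0)

    def test_hypergeometric_example(self):
        # background 10, term 4, query 5, overlap 4: p = C(4,4)C(6,1)/C(10,5)
        bg = {f"g{i}" for i in range(10)}
        term = {f"g{i}" for i in range(4)}
        query = {f"g{i}" for i in range(4)} | {"g9"}
        res = tx.overrepresentation(query, bg, {"t": term})
        assert res.loc["t", "p"] == pytest.approx(6 / 252, abs=1e-12)

    def test_single_term_adjustment_identity(self):
        bg = {f"g{i}" for i in range(10)}
        res = tx.overrepresentation({"g0", "g1"}, bg, {"t": {"g0", "g5"}})
        assert res.loc["t", "adj_p"] == pytest.approx(res.loc["t", "p"], abs=1e-15)

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError):
            tx.overrepresentation({"zz"}, {"g0"}, {})

    def test_fisher_p_matches_exact_enumeration_small_grid(self):
        # exhaustive integer-arithmetic oracle on a sample of table sizes
        for N in (5, 17, 33):
            for K in range(N + 1):
                for n in range(N + 1):
                    lo = max(0, n + K - N)
                    hi = min(n, K)
                    denom = math.comb(N, n)
                    for k in range(lo, hi + 1):
                        numer = sum(math.comb(K, j) * math.comb(N - K, n - j)
                                    for j in range(k, hi + 1))
                        p = tx.fisher_enrichment_p(k, N, K, n)
                        assert abs(p - numer / denom) < 1e-12

    def test_annotation_coverage(self):
        bg = {f"g{i}" for i in range(100)}
        ann = {"t1": {f"g{i}" for i in range(50)},
               "t2": {f"g{i}" for i in range(40, 84)} | {"external"}}
        assert tx.annotation_coverage(bg, ann) == pytest.approx(84.0)

    @given(st.lists(st.floats(1e-12, 1.0), min_size=3, max_size=30))
    def test_bh_adjustment_permutation_invariant(self, pvals):
        from statsmodels.stats.multitest import multipletests
        p = np.array(pvals)
        adj = multipletests(p, method="fdr_bh")[1]
        perm = np.random.default_rng(0).permutation(len(p))
        adj_perm = multipletests(p[perm], method="fdr_bh")[1]
        np.testing.assert_allclose(adj[perm], adj_perm, atol=1e-15)


class TestPCA:
    def _norm(self, x):
        cpm = pd.DataFrame(x, index=[f"g{i}" for i in range(x.shape[0])],
                           columns=[f"s{j}" for j in range(x.shape[1])])
        samples = pd.DataFrame({"genotype": ["FVB"] * x.shape[1],
                                "age": [4] * x.shape[1]}, index=cpm.columns)
        return tx.NormalizationResult(factors=pd.Series(1.0, index=cpm.columns),
                                      lib_sizes=pd.Series(1e6, index=cpm.columns),
                                      cpm=cpm, samples=samples)

    def test_rank_invariance_under_monotone_transform(self, rng):
        x = rng.gamma(2.0, 2.0, size=(20, 8))
        genes = [f"g{i}" for i in range(20)]
        a = tx.ageing_pca(self._norm(x), genes)
        b = tx.ageing_pca(self._norm(np.exp(x / x.max())), genes)
        np.testing.assert_allclose(a.scores.to_numpy(), b.scores.to_numpy(),
                                   atol=1e-9)

    def test_duplicate_samples_get_equal_scores(self, rng):
        x = rng.gamma(2.0, 2.0, size=(15, 6))
        x[:, 5] = x[:, 4]
        res = tx.ageing_pca(self._norm(x), [f"g{i}" for i in range(15)])
        np.testing.assert_allclose(res.scores.iloc[4], res.scores.iloc[5],
                                   atol=1e-9)

    def test_two_clusters_split_on_pc1(self, rng):
        x = rng.normal(10.0, 0.3, size=(30, 10))
        x[:15, 5:] += 5.0           # strong two-cluster structure
        res = tx.ageing_pca(self._norm(np.abs(x)), [f"g{i}" for i in range(30)])
        pc1 = res.scores["PC1"].to_numpy()
        assert len(set(np.sign(pc1[:5]))) == 1
        assert len(set(np.sign(pc1[5:]))) == 1
        assert np.sign(pc1[0]) != np.sign(pc1[-1])

    def test_variance_fractions_non_increasing_and_scores_centred(self, rng):
        x = rng.gamma(2.0, 2.0, size=(12, 7))
        res = tx.ageing_pca(self._norm(x), [f"g{i}" for i in range(12)])
        assert (np.diff(res.variance_fractions) <= 1e-12).all()
        assert res.variance_fractions.sum() <= 1.0 + 1e-9
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-9)

    def test_constant_gene_dropped_with_warning(self, rng):
        x = rng.gamma(2.0, 2.0, size=(5, 6))
        x[2] = 7.0
        with pytest.warns(RuntimeWarning, match="constant"):
            res = tx.ageing_pca(self._norm(x), [f"g{i}" for i in range(5)])
        assert "g2" not in res.genes_used


class TestChainRecovery:
    def test_planted_signature_recovered_end_to_end(self):
        cfg = CountSimConfig(
            n_genes=4000, nb_dispersion=0.05, seed=11,
            groups=tuple((g, a, 5) for g in ("FVB", "Tgaq44")
                         for a in (4, 6, 8, 10, 12, 14)))
        cm, truth = gen_count_matrix(cfg)
        norm = tx.normalize_counts(cm)
        kept = tx.filter_genes(norm)
        deg = {a: tx.deg_set(tx.differential_expression(
            norm, cm.samples_of("FVB", a), cm.samples_of("FVB", 4), genes=kept))
            for a in (6, 8, 10, 12, 14)}
        part = tx.classify_ageing_genes(deg)
        t_aged = set(truth.params["memberships"]["aged_only"])
        t_ageing = set(truth.params["memberships"]["ageing"])
        assert len(part.aged_only & t_aged) / len(t_aged) >= 0.90
        assert len(part.ageing & t_ageing) / len(t_ageing) >= 0.90
        assert len(part.aged_only - t_aged) <= 0.05 * max(len(part.aged_only), 1)
        assert len(part.ageing - t_ageing) <= 0.05 * max(len(part.ageing), 1)


class TestIO:
    def test_counts_tsv_roundtrip(self, tmp_path):
        cfg = CountSimConfig(n_genes=50, groups=(("FVB", 4, 3),),
                             planted_sets=(), seed=0)
        cm, _ = gen_count_matrix(cfg)
        tx.write_counts_tsv(cm, tmp_path / "c.tsv", tmp_path / "s.tsv")
        back = tx.read_counts_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        pd.testing.assert_frame_equal(back.counts, cm.counts)

    def test_gmt_reader(self, tmp_path):
        path = tmp_path / "ann.gmt"
        path.write_text("term1\tdesc\tg1\tg2\ng3\nterm2\t\tg2\n")
        ann = tx.read_gmt(path)
        assert ann["term1"] == {"g1", "g2"}
        assert ann["term2"] == {"g2"}
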