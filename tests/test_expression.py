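import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyfam.expression import (
    CountMatrix,
    Dendrogram,
    bh_adjust,
    call_degs,
    categorize_expression_breadth,
    classify_homoeolog_expression,
    filter_low_expression,
    hierarchical_cluster,
    log_cpm,
    moderated_t_test,
    pearson_matrix,
    tmm_factors,
    voom_weights,
)
from polyfam.homoeology import HomoeologGroup
from polyfam.models import ExpressionSampleMeta


def _meta(n, tissue="leaf", treatments=None):
    out = []
    for i in range(n):
        treatment = treatments[i] if treatments else ("control" if i < n // 2 else "heat")
        out.append(
            ExpressionSampleMeta(f"s{i}", tissue, treatment, "1h", i % 3 + 1)
        )
    return out


def _matrix(values, genes=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=genes, columns=[f"s{i}" for i in range(values.shape[1])])
    return CountMatrix(df, _meta(values.shape[1]))


class TestFilter:
    def test_all_zero_gene_removed(self):
        cm = _matrix([[0, 0, 0, 0], [50, 60, 70, 80]])
        kept = filter_low_expression(cm, min_samples=3)
        assert list(kept.counts.index) == ["g1"]

    def test_well_expressed_gene_kept(self):
        cm = _matrix(np.full((5, 6), 100))
        kept = filter_low_expression(cm)
        assert kept.n_genes == 5

    def test_planted_silent_genes_exactly_removed(self, small_sim_counts):
        counts, samples, truth = small_sim_counts
        cm = CountMatrix(counts, samples)
        kept = filter_low_expression(cm)
        removed = set(cm.counts.index) - set(kept.counts.index)
        assert removed == set(truth.silent_genes)

    def test_min_samples_validation(self):
        cm = _matrix([[1, 2], [3, 4]])
        with pytest.raises(ValueError):
            filter_low_expression(cm, min_samples=5)


class TestTmm:
    def test_identical_libraries(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(100, size=300)
        cm = _matrix(np.tile(col[:, None], (1, 3)))
        assert tmm_factors(cm) == pytest.approx(np.ones(3))

    def test_proportional_libraries(self):
        rng = np.random.default_rng(2)
        col = rng.poisson(100, size=300) + 1
        cm = _matrix(np.column_stack([col, 2 * col]))
        assert tmm_factors(cm) == pytest.approx(np.ones(2))

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(3)
        cm = _matrix(rng.poisson(rng.uniform(10, 500, size=(200, 1)), size=(200, 4)))
        f = tmm_factors(cm)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)

    def test_matches_stepwise_hand_computation(self):
        # a small matrix worked through the documented formula with plain
        # Python loops (trim by rank, inverse-variance weights)
        counts = np.array(
            [
                [100, 180, 90],
                [200, 410, 220],
                [50, 100, 45],
                [400, 790, 390],
                [80, 170, 85],
                [1000, 2100, 980],
                [300, 620, 310],
                [25, 60, 20],
                [700, 1350, 690],
                [150, 330, 140],
                [60, 130, 65],
                [450, 900, 430],
            ],
            dtype=float,
        )
        cm = _matrix(counts.astype(int))
        factors = tmm_factors(cm, trim_m=0.3, trim_a=0.05)

        lib = counts.sum(axis=0)
        f75 = np.array([np.percentile(counts[:, j], 75) for j in range(3)]) / lib
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
        expected = np.ones(3)
        for j in range(3):
            if j == ref:
                continue
            pj, pr = counts[:, j] / lib[j], counts[:, ref] / lib[ref]
            m = np.log2(pj / pr)
            a = 0.5 * np.log2(pj * pr)
            v = (lib[j] - counts[:, j]) / (lib[j] * counts[:, j]) + (
                lib[ref] - counts[:, ref]
            ) / (lib[ref] * counts[:, ref])
            n = len(m)
            keep = np.ones(n, bool)
            lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
            lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
            rm, ra = stats.rankdata(m), stats.rankdata(a)
            keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
            expected[j] = 2 ** (np.sum(m[keep] / v[keep]) / np.sum(1 / v[keep]))
        expected /= np.exp(np.mean(np.log(expected)))
        assert factors == pytest.approx(expected, abs=1e-8)

    def test_matches_edger_reference_implementation(self, tmp_path):
        """Cross-check against the Bioconductor reference on a toy matrix."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(4)
        counts = rng.negative_binomial(5, 0.02, size=(150, 4)) + 1
        cm = _matrix(counts)
        ours = tmm_factors(cm)
        csv = tmp_path / "counts.csv"
        pd.DataFrame(counts).to_csv(csv, index=False)
        script = tmp_path / "tmm.R"
        script.write_text(
            "suppressMessages(library(edgeR))\n"
            f"x <- as.matrix(read.csv('{csv}'))\n"
            "f <- calcNormFactors(x, method='TMM')\n"
            "cat(f, sep='\\n')\n"
        )
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True,
            timeout=120,
        )
        if proc.returncode != 0:
            pytest.skip(f"edgeR unavailable: {proc.stderr[:200]}")
        theirs = np.array([float(x) for x in proc.stdout.split()])
        assert ours == pytest.approx(theirs, rel=0.02)

    def test_zero_library_is_error(self):
        cm = _matrix([[0, 5], [0, 5]])
        with pytest.raises(ValueError):
            tmm_factors(cm)


class TestLogCpm:
    def test_closed_form_zero_count(self):
        counts = np.zeros((1, 2), dtype=int)
        counts[0, 1] = 10 ** 6  # to fix the library size of sample 1
        cm = _matrix(np.array([[0, 0], [10 ** 6, 10 ** 6]]))
        norm = log_cpm(cm, np.ones(2))
        expected = np.log2(0.5 / (10 ** 6 + 1) * 1e6)
        assert norm.logcpm.iloc[0, 0] == pytest.approx(expected, abs=1e-6)

    def test_monotone_within_sample(self):
        cm = _matrix([[10, 10], [20, 10], [500, 10]])
        norm = log_cpm(cm)
        col = norm.logcpm.iloc[:, 0].values
        assert col[0] < col[1] < col[2]

    def test_depth_invariance_for_large_counts(self):
        # the prior count shrinks toward zero as counts grow; at >= 100
        # reads the doubling effect is below 0.01 log2 units
        rng = np.random.default_rng(5)
        base = rng.integers(100, 1000, size=(100, 1))
        cm1 = _matrix(np.tile(base, (1, 2)))
        cm2 = _matrix(np.tile(base * 2, (1, 2)))
        n1 = log_cpm(cm1).logcpm.values
        n2 = log_cpm(cm2).logcpm.values
        assert np.max(np.abs(n1 - n2)) < 0.01


class TestVoom:
    def test_weights_positive_finite(self, small_sim_counts):
        counts, samples, _truth = small_sim_counts
        cm = filter_low_expression(CountMatrix(counts, samples))
        norm = log_cpm(cm, tmm_factors(cm))
        w = voom_weights(norm, [s.tissue for s in samples])
        assert np.isfinite(w.values).all() and (w.values > 0).all()

    def test_homoskedastic_weights_nearly_flat(self):
        rng = np.random.default_rng(6)
        y = rng.normal(8, 1, size=(2000, 6))
        counts = np.maximum(np.round(2 ** y), 1).astype(int)
        cm = _matrix(counts)
        norm = log_cpm(cm)
        w = voom_weights(norm, ["a", "a", "a", "b", "b", "b"])
        mid = w.values[(norm.logcpm.values.mean(axis=1) > np.quantile(
            norm.logcpm.values.mean(axis=1), 0.1))]
        assert mid.max() / mid.min() < 4.0

    def test_decreasing_variance_gives_increasing_weights(self):
        rng = np.random.default_rng(7)
        n = 3000
        means = rng.uniform(2, 12, size=n)
        sds = 1.5 - 0.1 * means  # strong decreasing mean-variance trend
        y = means[:, None] + rng.normal(0, sds[:, None].clip(0.05), size=(n, 6))
        counts = np.maximum(np.round(2 ** y), 0).astype(int)
        cm = _matrix(counts)
        norm = log_cpm(cm)
        w = voom_weights(norm, ["a", "a", "a", "b", "b", "b"])
        mean_count = norm.logcpm.values.mean(axis=1)
        lo = w.values[mean_count < np.quantile(mean_count, 0.2)].mean()
        hi = w.values[mean_count > np.quantile(mean_count, 0.8)].mean()
        assert hi > lo

    def test_all_singleton_groups_is_error(self):
        cm = _matrix(np.full((20, 3), 50))
        norm = log_cpm(cm)
        with pytest.raises(ValueError):
            voom_weights(norm, ["a", "b", "c"])


class TestModeratedT:
    def _norm(self, y):
        counts = np.maximum(np.round(2 ** y), 0).astype(int)
        cm = _matrix(counts)
        return log_cpm(cm)

    def test_identical_group_means_give_t_zero(self):
        from polyfam.expression import NormalizedMatrix

        y = np.random.default_rng(8).normal(8, 0.3, size=(30, 6))
        y[0] = [8, 9, 10, 8, 9, 10]  # identical values in both groups
        df = pd.DataFrame(y, index=[f"g{i}" for i in range(30)],
                          columns=[f"s{i}" for i in range(6)])
        norm = NormalizedMatrix(df, np.ones(6), np.ones(6))
        res = moderated_t_test(norm, ["c", "c", "c", "h", "h", "h"], ("h", "c"))
        assert res.table.iloc[0]["moderated_t"] == pytest.approx(0.0, abs=1e-12)
        assert res.table.iloc[0]["p"] == pytest.approx(1.0)

    def test_prior_df_zero_reduces_to_ordinary_t(self):
        rng = np.random.default_rng(9)
        norm = self._norm(rng.normal(8, 1, size=(500, 6)))
        res = moderated_t_test(
            norm, ["c", "c", "c", "h", "h", "h"], ("h", "c"), prior_df=0
        )
        assert np.allclose(
            res.table["moderated_t"].values, res.table["ordinary_t"].values
        )
        # and the p-values match the textbook two-sample t
        i = 17
        y = norm.logcpm.values[i]
        t, p = stats.ttest_ind(y[3:], y[:3])
        assert res.table.iloc[i]["ordinary_t"] == pytest.approx(t)
        assert res.table.iloc[i]["p"] == pytest.approx(p)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(10)
        norm = self._norm(rng.normal(8, 1, size=(4000, 6)))
        res = moderated_t_test(norm, ["c", "c", "c", "h", "h", "h"], ("h", "c"))
        ks = stats.kstest(res.table["p"].values, "uniform")
        assert ks.pvalue > 0.01

    def test_too_few_replicates_is_error(self):
        rng = np.random.default_rng(11)
        norm = self._norm(rng.normal(8, 1, size=(50, 3)))
        with pytest.raises(ValueError):
            moderated_t_test(norm, ["c", "h", "h"], ("h", "c"))


class TestBh:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.031]) == pytest.approx([0.031])

    def test_step_up_by_hand(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestDegCalls:
    @pytest.mark.parametrize(
        "logfc,adjp,expected",
        [
            (1.2, 0.01, True),
            (1.0, 0.001, False),  # strict: |logFC| must exceed 1
            (-3.0, 0.049, True),
            (2.0, 0.05, False),  # strict: adjP must be below alpha
        ],
    )
    def test_rule(self, logfc, adjp, expected):
        from polyfam.expression import ContrastResult

        table = pd.DataFrame(
            {
                "logFC": [logfc], "mean_expr": [5.0], "ordinary_t": [1.0],
                "moderated_t": [1.0], "p": [adjp], "adjP": [adjp], "is_deg": [False],
            },
            index=["g"],
        )
        res = call_degs(
            ContrastResult(table=table, contrast="x", d0=1, s0_sq=1, residual_df=4)
        )
        assert bool(res.table.iloc[0]["is_deg"]) is expected


class TestPearson:
    def _norm_from_values(self, values, genes):
        df = pd.DataFrame(values, index=genes,
                          columns=[f"s{i}" for i in range(values.shape[1])])
        from polyfam.expression import NormalizedMatrix

        return NormalizedMatrix(
            logcpm=df, tmm_factors=np.ones(values.shape[1]),
            lib_sizes=np.ones(values.shape[1]),
        )

    def test_diagonal_and_antisymmetry(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        norm = self._norm_from_values(np.vstack([x, -x]), ["a", "b"])
        corr = pearson_matrix(norm)
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        norm = self._norm_from_values(
            np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 4.0]]), ["x", "y"]
        )
        corr = pearson_matrix(norm)
        assert corr.loc["x", "y"] == pytest.approx(0.9820, abs=1e-4)

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(13)
        norm = self._norm_from_values(rng.normal(size=(20, 10)),
                                      [f"g{i}" for i in range(20)])
        corr = pearson_matrix(norm)
        eigenvalues = np.linalg.eigvalsh(corr.values)
        assert eigenvalues.min() > -1e-8

    def test_too_few_samples_is_error(self):
        norm = self._norm_from_values(np.ones((3, 2)), ["a", "b", "c"])
        with pytest.raises(ValueError):
            pearson_matrix(norm)


class TestHierarchicalClustering:
    def test_identical_profiles_merge_at_zero(self):
        df = pd.DataFrame([[1, 2, 3], [1, 2, 3], [9, 9, 9]],
                          index=["a", "b", "c"], dtype=float)
        dend = hierarchical_cluster(df)
        assert dend.linkage[0, 2] == pytest.approx(0.0)

    def test_hand_computed_upgma_heights(self):
        # three points with pairwise distances 1, 1, 2
        df = pd.DataFrame([[0.0], [1.0], [-1.0]], index=["a", "b", "c"])
        dend = hierarchical_cluster(df)
        heights = sorted(dend.linkage[:, 2])
        assert heights[0] == pytest.approx(1.0)
        assert heights[1] == pytest.approx(1.5)

    def test_heights_monotone_nondecreasing(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame(rng.normal(size=(25, 6)))
        df.index = [f"g{i}" for i in range(25)]
        dend = hierarchical_cluster(df)
        assert (np.diff(dend.linkage[:, 2]) >= -1e-12).all()

    def test_newick_is_well_formed(self):
        df = pd.DataFrame([[0.0], [1.0], [-1.0], [5.0]], index=list("abcd"))
        nwk = hierarchical_cluster(df).newick()
        assert nwk.endswith(";")
        assert nwk.count("(") == 3
        for label in "abcd":
            assert label in nwk


class TestHomoeologExpression:
    def _norm(self, means):
        # constant per-gene profiles on the linear scale
        values = np.log2(np.array(means, dtype=float))[:, None] * np.ones((1, 4))
        genes = [f"m{i}" for i in range(len(means))]
        df = pd.DataFrame(values, index=genes,
                          columns=[f"s{i}" for i in range(4)])
        from polyfam.expression import NormalizedMatrix

        return NormalizedMatrix(df, np.ones(4), np.ones(4))

    def _group(self, n):
        subs = ["A", "B", "D"][:n]
        return HomoeologGroup("G0", "triplet" if n == 3 else "pair", 1,
                              [(f"m{i}", subs[i]) for i in range(n)])

    def test_equal_means_similar(self):
        call = classify_homoeolog_expression(self._group(3), self._norm([100, 100, 100]))
        assert call.call == "similar" and call.silenced_or_divergent == []

    def test_silenced_member_partitioned(self):
        call = classify_homoeolog_expression(self._group(3), self._norm([100, 90, 2]))
        assert call.call == "partitioned"
        assert "m2" in call.silenced_or_divergent

    def test_twofold_pair_partitioned(self):
        call = classify_homoeolog_expression(self._group(2), self._norm([100, 45]))
        assert call.call == "partitioned"

    def test_planted_partitioned_triplets_recovered(self, small_sim_counts):
        counts, samples, truth = small_sim_counts
        cm = filter_low_expression(CountMatrix(counts, samples))
        norm = log_cpm(cm, tmm_factors(cm))
        groups = {g["group_id"]: g for g in truth.homoeolog_groups}
        for rec in truth.partitioned_triplets:
            g = groups[rec["group_id"]]
            group = HomoeologGroup(
                g["group_id"], g["kind"], g["chromosome_number"],
                [(m["gene_id"], m["subgenome"]) for m in g["members"]],
            )
            call = classify_homoeolog_expression(group, norm)
            assert call.call == "partitioned"
            assert rec["silenced_member"] in call.silenced_or_divergent


class TestBreadth:
    def _norm(self, values, genes, tissues):
        df = pd.DataFrame(values, index=genes,
                          columns=[f"s{i}" for i in range(values.shape[1])])
        from polyfam.expression import NormalizedMatrix

        return NormalizedMatrix(df, np.ones(values.shape[1]),
                                np.ones(values.shape[1])), tissues

    def test_constitutive_specific_and_weak(self):
        tissues = ["grain", "grain", "spike", "spike", "leaf", "leaf", "root", "root"]
        values = np.array(
            [
                [6, 6, 6, 6, 6, 6, 6, 6],          # constitutive
                [10, 10, 2, 2, 2, 2, 2, 2],        # grain-specific
                [0, 0, 0, 0, 0, 0, 0, 0],          # below floor everywhere
            ],
            dtype=float,
        )
        norm, tissues = self._norm(values, ["c", "g", "w"], tissues)
        out = categorize_expression_breadth(norm, tissues)
        assert out.loc["c", "category"] == "constitutive"
        assert out.loc["g", "category"] == "tissue_specific(grain)"
        assert out.loc["w", "category"] == "other"
        assert out.loc["w", "level"] == "weak"

    def test_needs_two_tissues(self):
        norm, tissues = self._norm(np.ones((2, 2)), ["a", "b"], ["leaf", "leaf"])
        with pytest.raises(ValueError):
            categorize_expression_breadth(norm, tissues)
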