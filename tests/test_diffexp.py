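"""Moderated t, BH-FDR, DE filters, centroid score, metagenes, Fisher exact."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import polygamma

from tksig.diffexp import (CentroidScore, DEGeneList, ModeratedTestResult,
                           association_tests, bh_fdr, centroid_score,
                           de_gene_list, estimate_variance_prior,
                           fisher_exact_rxc, metagene_score, moderated_t,
                           trigamma_inverse)


def two_group_matrix(n_genes=200, n1=6, n2=6, seed=0, shift_genes=0, shift=1.0,
                     var_prior=None):
    rng = np.random.default_rng(seed)
    if var_prior is None:
        sigma2 = np.ones(n_genes)
    else:
        d0, s0_sq = var_prior
        sigma2 = s0_sq * d0 / rng.chisquare(d0, n_genes)
    X = rng.normal(size=(n_genes, n1 + n2)) * np.sqrt(sigma2)[:, None]
    X[:shift_genes, :n1] += shift
    cols = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    matrix = pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)],
                          columns=cols)
    labels = pd.Series(["A"] * n1 + ["B"] * n2, index=cols)
    return matrix, labels


class TestModeratedT:
    def test_closed_form_with_fixed_prior(self):
        # one gene with logFC = 1, pooled s2 = 1, n1 = n2 = 3; prior (3, 1):
        # s2_post = (3*1 + 4*1)/7 = 1, t = 1/sqrt(2/3), df = 7
        a = np.array([0.0, 1.0, 2.0])       # mean 1, var 1
        b = np.array([-1.0, 0.0, 1.0])      # mean 0, var 1
        mat = pd.DataFrame([np.r_[a, b], np.r_[a * 0.5, b * 0.5]],
                           index=["g1", "g2"],
                           columns=[f"s{i}" for i in range(6)])
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=mat.columns)
        res = moderated_t(mat, labels, ("A", "B"), prior=(3.0, 1.0))
        row = res.table.loc["g1"]
        assert row["logFC"] == pytest.approx(1.0)
        assert row["s2"] == pytest.approx(1.0)
        assert row["t_mod"] == pytest.approx(1.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert row["df_total"] == 7.0
        expected_p = 2 * stats.t.sf(1.0 / np.sqrt(2.0 / 3.0), 7)
        assert row["p"] == pytest.approx(expected_p, rel=1e-12)

    def test_zero_prior_df_equals_ordinary_pooled_t(self):
        matrix, labels = two_group_matrix(seed=1, shift_genes=20)
        res = moderated_t(matrix, labels, ("A", "B"), prior=(0.0, 1.0))
        t_ref, p_ref = stats.ttest_ind(matrix.iloc[:, :6], matrix.iloc[:, 6:],
                                       axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["t_mod"], t_ref, rtol=1e-12)
        np.testing.assert_allclose(res.table["p"], p_ref, rtol=1e-12)

    def test_infinite_prior_ranks_by_fold_change(self):
        matrix, labels = two_group_matrix(seed=2)
        res = moderated_t(matrix, labels, ("A", "B"), prior=(np.inf, 1.0))
        by_t = res.table["t_mod"].abs().rank()
        by_fc = res.table["logFC"].abs().rank()
        pd.testing.assert_series_equal(by_t, by_fc, check_names=False)

    def test_prior_recovery_at_scale(self):
        """Moment estimator recovers (d0, s0_sq) from 5000 genes."""
        matrix, labels = two_group_matrix(n_genes=5000, n1=4, n2=4, seed=3,
                                          var_prior=(4.0, 0.25))
        res = moderated_t(matrix, labels, ("A", "B"))
        assert 2.0 <= res.d0 <= 8.0
        assert abs(res.s0_sq - 0.25) / 0.25 < 0.25

    def test_equal_true_variances_give_large_prior_df(self):
        matrix, labels = two_group_matrix(n_genes=3000, n1=8, n2=8, seed=4)
        res = moderated_t(matrix, labels, ("A", "B"))
        assert np.isinf(res.d0) or res.d0 > 20

    def test_zero_variance_gene_rescued_by_shrinkage(self):
        matrix, labels = two_group_matrix(seed=5, var_prior=(4.0, 0.25))
        matrix.iloc[0] = np.r_[np.ones(6), np.zeros(6)]  # constant per group
        res = moderated_t(matrix, labels, ("A", "B"))
        assert np.isfinite(res.table["t_mod"].iloc[0])
        assert res.table["p"].iloc[0] < 0.01

    def test_trigamma_inverse_roundtrip(self):
        for x in (0.1, 0.5, 2.0, 10.0, 100.0):
            y = float(polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)

    def test_matches_limma_on_small_matrix(self, tmp_path):
        """R limma (lmFit + eBayes) as independent oracle."""
        matrix, labels = two_group_matrix(n_genes=60, n1=5, n2=5, seed=6,
                                          shift_genes=10, var_prior=(5.0, 0.5))
        matrix.round(8).to_csv(tmp_path / "m.tsv", sep="\t")
        script = textwrap.dedent("""
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("m.tsv", row.names = 1))
            group <- factor(c(rep("A", 5), rep("B", 5)), levels = c("B", "A"))
            design <- model.matrix(~group)
            fit <- eBayes(lmFit(m, design))
            out <- data.frame(t = fit$t[, 2], p = fit$p.value[, 2],
                              lfc = fit$coefficients[, 2])
            write.table(out, "limma_out.tsv", sep = "\t", quote = FALSE)
            cat(fit$df.prior, fit$s2.prior, sep = "\n")
        """)
        (tmp_path / "run.R").write_text(script)
        res = subprocess.run(["Rscript", "run.R"], cwd=tmp_path,
                             capture_output=True, text=True, check=True)
        d0_r, s0_r = [float(x) for x in res.stdout.split()]
        ref = pd.read_csv(tmp_path / "limma_out.tsv", sep="\t", index_col=0)
        mine = moderated_t(matrix, labels, ("A", "B"))
        np.testing.assert_allclose(mine.table["logFC"], ref["lfc"], rtol=1e-6)
        assert mine.d0 == pytest.approx(d0_r, rel=1e-4)
        assert mine.s0_sq == pytest.approx(s0_r, rel=1e-4)
        np.testing.assert_allclose(mine.table["t_mod"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(mine.table["p"], ref["p"], rtol=1e-6)


class TestBH:
    def test_all_equal_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.3] * 5), [0.3] * 5)

    def test_hand_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_identity(self):
        np.testing.assert_allclose(bh_fdr([0.123]), [0.123])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_fdr(p), ref, rtol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestDEList:
    def make_result(self, logfc, p, q):
        table = pd.DataFrame({
            "logFC": logfc, "s2": 1.0, "t_mod": 1.0, "df_total": 10.0,
            "p": p, "q": q,
        }, index=[f"g{i}" for i in range(len(logfc))])
        return ModeratedTestResult(table=table, d0=4.0, s0_sq=1.0,
                                   groups=("low", "high"))

    def test_joint_thresholds(self):
        res = self.make_result(
            logfc=[0.5, -0.5, 0.1, 0.5, 0.5, -0.4],
            p=[1e-3, 1e-3, 1e-3, 0.5, 1e-3, 1e-3],
            q=[1e-3, 1e-3, 1e-3, 1e-3, 0.5, 1e-3])
        de = de_gene_list(res)
        assert de.up_in_first == ["g0"]
        assert de.up_in_second == ["g1", "g5"]

    def test_fc_one_keeps_any_nonzero_fold_change(self):
        res = self.make_result(logfc=[0.01, 0.0], p=[1e-4, 1e-4], q=[1e-4, 1e-4])
        de = de_gene_list(res, fc_min=1.0)
        assert de.up_in_first == ["g0"] and de.up_in_second == []

    def test_randomized_labels_yield_empty_lists(self):
        sizes = []
        for seed in range(5):
            matrix, labels = two_group_matrix(n_genes=300, n1=10, n2=10,
                                              seed=seed + 50)
            res = moderated_t(matrix, labels, ("A", "B"))
            de = de_gene_list(res)
            sizes.append(len(de.up_in_first) + len(de.up_in_second))
        assert np.mean(sizes) < 1.0


class TestCentroid:
    def test_centroid_samples_score_signs(self):
        rng = np.random.default_rng(0)
        mat, labels = two_group_matrix(n_genes=30, n1=10, n2=10, seed=7,
                                       shift_genes=30, shift=2.0)
        cs = centroid_score(mat, labels, ("A", "B"),
                            new_matrix=pd.DataFrame(
                                {"chA": mat.loc[:, (labels == "A").to_numpy()].median(axis=1),
                                 "chB": mat.loc[:, (labels == "B").to_numpy()].median(axis=1)}))
        assert cs.scores.loc["chA", "score"] > 0
        assert cs.scores.loc["chB", "score"] < 0
        assert cs.scores.loc["chA", "predicted"] == "A"

    def test_separation_on_held_out_samples(self):
        # the class difference must vary across genes (up- and down-regulated
        # members) for a correlation-based score to see it
        def make(seed, n1, n2):
            mat, labels = two_group_matrix(n_genes=40, n1=n1, n2=n2, seed=seed)
            mat.iloc[:20, :n1] += 1.0
            mat.iloc[20:, :n1] -= 1.0
            mat.iloc[:20, n1:] -= 1.0
            mat.iloc[20:, n1:] += 1.0
            return mat, labels

        mat, labels = make(8, 30, 30)
        new, new_labels = make(9, 25, 25)
        new.columns = [f"n{i}" for i in range(50)]
        new_labels.index = new.columns
        cs = centroid_score(mat, labels, ("A", "B"), new_matrix=new,
                            new_labels=new_labels)
        mean_a = cs.scores.loc[(new_labels == "A").to_numpy(), "score"].mean()
        mean_b = cs.scores.loc[(new_labels == "B").to_numpy(), "score"].mean()
        assert mean_a > mean_b
        assert cs.ttest_p < 0.01
        acc = (cs.scores["predicted"] == new_labels.loc[cs.scores.index]).mean()
        assert acc > 0.9

    def test_too_few_genes_rejected(self):
        mat, labels = two_group_matrix(n_genes=2, seed=10)
        with pytest.raises(ValueError, match=">= 3 genes"):
            centroid_score(mat, labels, ("A", "B"), new_matrix=mat)

    def test_flat_profile_flagged(self):
        mat, labels = two_group_matrix(n_genes=10, seed=11)
        new = mat.iloc[:, :2].copy()
        new.iloc[:, 0] = 5.0
        cs = centroid_score(mat, labels, ("A", "B"), new_matrix=new)
        assert np.isnan(cs.scores["score"].iloc[0])
        assert np.isfinite(cs.scores["score"].iloc[1])


class TestMetagene:
    def test_single_gene_set_equals_zscore(self):
        mat, _ = two_group_matrix(n_genes=5, seed=12)
        score = metagene_score(mat, ["g2"])
        x = mat.loc["g2"]
        expected = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(score, expected, rtol=1e-12)

    def test_anticorrelated_pair_cancels(self):
        cols = [f"s{i}" for i in range(10)]
        x = np.linspace(-1, 1, 10)
        mat = pd.DataFrame([x, -x], index=["up", "dn"], columns=cols)
        score = metagene_score(mat, ["up", "dn"])
        np.testing.assert_allclose(score, 0.0, atol=1e-12)

    def test_missing_members_dropped_and_empty_overlap_raises(self):
        mat, _ = two_group_matrix(n_genes=5, seed=13)
        s = metagene_score(mat, ["g0", "NOT_THERE"], set_name="demo")
        np.testing.assert_allclose(
            s, metagene_score(mat, ["g0"]), rtol=1e-12)
        with pytest.raises(KeyError, match="demo2"):
            metagene_score(mat, ["NOPE"], set_name="demo2")

    def test_gmt_scores_deterministic(self, tmp_path):
        from tksig.io import read_gmt

        gmt = tmp_path / "sets.gmt"
        gmt.write_text("setA\tdesc\tg0\tg1\nsetB\tdesc\tg2\nsetC\tdesc\tg3\tg4\n")
        sets = read_gmt(gmt)
        assert list(sets) == ["setA", "setB", "setC"]
        mat, _ = two_group_matrix(n_genes=5, seed=14)
        scores = pd.DataFrame({name: metagene_score(mat, genes, set_name=name)
                               for name, genes in sets.items()})
        scores2 = pd.DataFrame({name: metagene_score(mat, genes, set_name=name)
                                for name, genes in sets.items()})
        pd.testing.assert_frame_equal(scores, scores2)
        assert scores.shape == (12, 3)


class TestFisherAndAssociations:
    def test_two_by_two_hand_enumeration(self):
        assert fisher_exact_rxc([[3, 1], [1, 3]]) == pytest.approx(34 / 70,
                                                                   rel=1e-10)

    def test_matches_scipy_on_random_2x2(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            table = rng.integers(0, 12, size=(2, 2))
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                continue
            _, ref = stats.fisher_exact(table)
            assert fisher_exact_rxc(table) == pytest.approx(ref, rel=1e-9)

    def test_proportional_rows_give_p_one(self):
        assert fisher_exact_rxc([[2, 2], [2, 2]]) == pytest.approx(1.0)

    def test_monte_carlo_close_to_exact_on_rxc(self):
        table = [[8, 3, 5], [2, 7, 4]]
        exact = fisher_exact_rxc(table)
        mc = fisher_exact_rxc(table, max_tables=1, n_mc=40_000, seed=1)
        assert abs(mc - exact) < 0.02

    def test_matches_r_fisher_on_rxc(self, tmp_path):
        script = 'cat(fisher.test(matrix(c(8,2,3,7,5,4), nrow=2))$p.value)'
        res = subprocess.run(["Rscript", "-e", script],
                             capture_output=True, text=True, check=True)
        ref = float(res.stdout.strip())
        assert fisher_exact_rxc([[8, 3, 5], [2, 7, 4]]) == pytest.approx(
            ref, rel=1e-6)

    def test_association_report_layout(self):
        rng = np.random.default_rng(3)
        n = 120
        ids = [f"s{i}" for i in range(n)]
        labels = pd.Series(rng.choice(["low-risk", "high-risk"], n), index=ids)
        clinical = pd.DataFrame({
            "grade": rng.choice([1, 2, 3], n, p=[0.1, 0.2, 0.7]),
            "age_years": rng.normal(55, 10, n),
            "onelevel": ["x"] * n,
        }, index=ids)
        rep = association_tests(labels, clinical)
        grade_rows = rep[rep["variable"] == "grade"]
        for cls in ("low-risk", "high-risk"):
            assert abs(grade_rows[f"pct_{cls}"].sum() - 100) <= 2  # rounding
        assert (rep.loc[rep["variable"] == "onelevel", "test"] == "skipped").all()
        age_row = rep[rep["variable"] == "age_years"].iloc[0]
        a = clinical.loc[labels == "low-risk", "age_years"]
        b = clinical.loc[labels == "high-risk", "age_years"]
        assert age_row["p"] == pytest.approx(
            stats.ttest_ind(b, a, equal_var=False).pvalue, rel=1e-9)
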