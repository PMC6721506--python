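"""Harmonization: probe collapse, anchor z-scoring, receptor calls, subtyping."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from tksig.harmonize import (ExpressionStudy, HarmonizedCohort, NotBimodalError,
                             assign_subtype, call_receptor, collapse_probes,
                             select_subgroup, zscore_by_anchor)

from conftest import make_tn_cohort


def probe_study(rows, probe_map=None):
    mat = pd.DataFrame(rows).astype(float)
    mat.columns = [f"s{i}" for i in range(mat.shape[1])]
    return ExpressionStudy(matrix=mat + 8.0, platform="microarray",
                           dataset_id="D01", probe_map=probe_map)


class TestCollapseProbes:
    def test_highest_variance_probe_retained(self):
        rows = pd.DataFrame({
            "p_lo": [0.1, -0.1, 0.0, 0.1, -0.1, 0.0],
            "p_hi": [2.0, -2.0, 1.5, -1.5, 1.0, -1.0],
            "p_single": [0.5, 0.4, 0.3, 0.2, 0.1, 0.0],
        }).T
        study = probe_study(rows, probe_map={"p_lo": "G1", "p_hi": "G1",
                                             "p_single": "G2"})
        out = collapse_probes(study)
        assert list(out.matrix.index) == ["G1", "G2"]
        np.testing.assert_allclose(out.matrix.loc["G1"],
                                   study.matrix.loc["p_hi"])
        assert out.provenance["probe_for_gene"]["G1"] == "p_hi"
        # single-probe gene passes through unchanged
        np.testing.assert_allclose(out.matrix.loc["G2"],
                                   study.matrix.loc["p_single"])

    def test_exact_tie_keeps_lexicographically_smaller_probe(self, caplog):
        vals = [1.0, -1.0, 0.5, -0.5, 0.25, -0.25]
        rows = pd.DataFrame({"p_b": vals, "p_a": vals}).T
        study = probe_study(rows, probe_map={"p_a": "G", "p_b": "G"})
        with caplog.at_level("WARNING"):
            out = collapse_probes(study)
        assert out.provenance["probe_for_gene"]["G"] == "p_a"
        assert any("variance tie" in r.message for r in caplog.records)

    def test_row_order_permutation_invariant(self):
        rng = np.random.default_rng(1)
        rows = pd.DataFrame(rng.normal(size=(6, 8)),
                            index=[f"p{i}" for i in range(6)])
        pmap = {f"p{i}": f"G{i % 3}" for i in range(6)}
        a = collapse_probes(ExpressionStudy(rows + 8, "microarray", "D", probe_map=pmap))
        shuffled = rows.sample(frac=1, random_state=2)
        b = collapse_probes(ExpressionStudy(shuffled + 8, "microarray", "D",
                                            probe_map=pmap))
        pd.testing.assert_frame_equal(a.matrix.sort_index(), b.matrix.sort_index())


class TestAnchorZscore:
    def make_study(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        mat = pd.DataFrame(rng.normal(8, 1, size=(5, n)),
                           index=[f"G{i}" for i in range(5)],
                           columns=[f"s{i}" for i in range(n)])
        return ExpressionStudy(mat, "microarray", "D01")

    def test_anchor_moments_are_zero_one(self):
        study = self.make_study()
        anchors = [f"s{i}" for i in range(10)]
        z = zscore_by_anchor(study, anchors)
        ref = z.matrix[anchors]
        np.testing.assert_allclose(ref.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(ref.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_location_shift_invariance(self):
        study = self.make_study()
        anchors = [f"s{i}" for i in range(10)]
        shifted = ExpressionStudy(study.matrix + 5.0, "microarray", "D01")
        pd.testing.assert_frame_equal(zscore_by_anchor(study, anchors).matrix,
                                      zscore_by_anchor(shifted, anchors).matrix,
                                      atol=1e-12, rtol=0)

    def test_idempotent_within_tolerance(self):
        study = self.make_study()
        anchors = [f"s{i}" for i in range(10)]
        once = zscore_by_anchor(study, anchors)
        twice = zscore_by_anchor(once, anchors)
        assert np.abs(once.matrix - twice.matrix).to_numpy().max() < 1e-9

    def test_batch_distortion_removed_exactly(self):
        """Anchor z-scores of the batched matrix equal those of the clean one."""
        bundle, cohort, _ = make_tn_cohort(
            seed=9, n_datasets=2, samples_per_dataset=80,
            batch_shift=(2.0, -1.0), batch_scale=(1.5, 0.8))
        anchors = bundle.truth.samples.index[bundle.truth.samples["anchor"]]
        for study in bundle.studies:
            clean = bundle.truth.batch_free[study.sample_ids]
            clean_study = ExpressionStudy(clean, study.platform, study.dataset_id)
            za = zscore_by_anchor(study, anchors).matrix
            zc = zscore_by_anchor(clean_study, anchors).matrix
            assert np.abs(za - zc).to_numpy().max() < 1e-9

    def test_few_anchors_falls_back_or_fails(self, caplog):
        study = self.make_study()
        with caplog.at_level("WARNING"):
            z = zscore_by_anchor(study, ["s0", "s1"])
        assert any("anchor" in r.message for r in caplog.records)
        with pytest.raises(ValueError, match="anchor"):
            zscore_by_anchor(study, ["s0", "s1"], hard_fail=True)

    def test_zero_anchor_sd_uses_all_sample_sd(self, caplog):
        study = self.make_study()
        anchors = [f"s{i}" for i in range(5)]
        study.matrix.loc["G0", anchors] = 8.0  # constant over anchors only
        with caplog.at_level("WARNING"):
            z = zscore_by_anchor(study, anchors)
        assert np.isfinite(z.matrix.loc["G0"]).all()


class TestReceptorCalling:
    def test_recovers_analytic_crossing_point(self):
        rng = np.random.default_rng(0)
        n = 500
        comp = rng.random(n) < 0.6
        x = np.where(comp, rng.normal(-2, 0.5, n), rng.normal(2, 0.5, n))
        values = pd.Series(x, index=[f"s{i}" for i in range(n)])
        thr, calls = call_receptor(values)
        # analytic posterior-0.5 point of the generating mixture
        f = lambda v: (0.6 * norm.pdf(v, -2, 0.5)
                       - 0.4 * norm.pdf(v, 2, 0.5))
        analytic = brentq(f, -2, 2)
        assert abs(thr.cutpoint - analytic) < 0.3
        truth = np.where(comp, "negative", "positive")
        assert (calls.to_numpy() == truth).mean() >= 0.98

    def test_constant_values_not_bimodal(self):
        values = pd.Series(np.full(50, 3.0))
        with pytest.raises(NotBimodalError, match="not bimodal"):
            call_receptor(values)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(-2, 0.5, 150), rng.normal(2, 0.5, 150)])
        values = pd.Series(x)
        thr0, calls0 = call_receptor(values)
        thr5, calls5 = call_receptor(values + 5.0)
        assert abs((thr5.cutpoint - thr0.cutpoint) - 5.0) < 0.15
        pd.testing.assert_series_equal(calls0, calls5)

    def test_manual_cutpoint_respected(self):
        values = pd.Series([0.0, 1.0, 2.0, 3.0])
        thr, calls = call_receptor(values, manual_cutpoint=1.5)
        assert list(calls) == ["negative", "negative", "positive", "positive"]

    def test_accuracy_despite_batch_distortion(self):
        """Per-dataset calling is robust to any affine batch parameters."""
        bundle, cohort, _ = make_tn_cohort(
            seed=13, n_datasets=2, samples_per_dataset=250,
            batch_shift=(3.0, -3.0), batch_scale=(0.5, 2.0),
            use_truth_anchors=True)
        truth = bundle.truth.samples
        for col, lab in (("er", "ER"), ("pr", "PR"), ("erbb2", "ERBB2")):
            pred = (cohort.receptor_calls[lab] == "positive").to_numpy()
            acc = (pred == truth.loc[cohort.receptor_calls.index, col]).mean()
            assert acc >= 0.95, f"{lab} accuracy {acc:.3f}"


class TestSubtype:
    @pytest.mark.parametrize("er, pr, erbb2, expected", [
        ("negative", "negative", "negative", "TN"),
        ("negative", "positive", "negative", "ER+/ERBB2-"),
        ("positive", "positive", "positive", "ERBB2+"),
        ("positive", "negative", "negative", "ER+/ERBB2-"),
        ("negative", "negative", "positive", "ERBB2+"),
    ])
    def test_mapping(self, er, pr, erbb2, expected):
        calls = pd.DataFrame({"ER": [er], "PR": [pr], "ERBB2": [erbb2]})
        assert assign_subtype(calls).iloc[0] == expected

    def test_missing_call_excluded(self, caplog):
        calls = pd.DataFrame({"ER": ["negative", np.nan],
                              "PR": ["negative", "negative"],
                              "ERBB2": ["negative", "negative"]})
        with caplog.at_level("WARNING"):
            subtype = assign_subtype(calls)
        assert subtype.iloc[0] == "TN" and pd.isna(subtype.iloc[1])


class TestSelectSubgroup:
    def make_cohort(self, n=10, n_missing_dfs=2):
        ids = [f"s{i}" for i in range(n)]
        mat = pd.DataFrame(np.zeros((3, n)) + np.arange(n),
                           index=["G0", "G1", "G2"], columns=ids)
        dfs = [np.nan] * n_missing_dfs + [10.0] * (n - n_missing_dfs)
        clin = pd.DataFrame({
            "dfs_months": dfs, "dfs_event": [1] * n,
            "os_months": [20.0] * n, "os_event": [0] * n,
            "platform": ["microarray"] * n,
        }, index=ids)
        calls = pd.DataFrame({"ER": "negative", "PR": "negative",
                              "ERBB2": "negative"}, index=ids)
        return HarmonizedCohort(
            matrix=mat, clinical=clin, receptor_calls=calls,
            subtype=pd.Series("TN", index=ids),
            anchor_flag=pd.Series(False, index=ids))

    def test_filter_arithmetic(self):
        out = select_subgroup(self.make_cohort(), "TN", "dfs")
        assert out.matrix.shape[1] == 8

    def test_empty_subgroup_errors(self):
        with pytest.raises(ValueError, match="ERBB2"):
            select_subgroup(self.make_cohort(), "ERBB2+", "dfs")

    def test_matches_truth_channel(self):
        """With truth-derived subtypes, selection equals truth TN ∩ informative."""
        bundle, cohort, _ = make_tn_cohort(seed=21, n_datasets=2,
                                           samples_per_dataset=100)
        truth = bundle.truth.samples.loc[cohort.matrix.columns]
        truth_subtype = truth["subtype_true"].replace(
            {"anchor": "ER+/ERBB2-", "other": "ER+/ERBB2-"})
        cohort_truth = HarmonizedCohort(
            matrix=cohort.matrix, clinical=cohort.clinical,
            receptor_calls=cohort.receptor_calls,
            subtype=truth_subtype, anchor_flag=cohort.anchor_flag)
        selected = set(select_subgroup(cohort_truth, "TN", "dfs").matrix.columns)
        clin = cohort.clinical
        informative = set(clin.index[(clin["dfs_months"] > 0)
                                     & clin["dfs_event"].notna()])
        expected = set(truth.index[truth["subtype_true"] == "TN"]) & informative
        assert selected == expected
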