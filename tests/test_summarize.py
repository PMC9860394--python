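import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptmquant import summarize
from ptmquant.summarize import (
    impute_aft,
    log_sum,
    median_polish,
    median_polish_summarize,
    ratio_summarize,
)


class TestLogSum:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([7.3], 7.3),  # single feature: identity
            ([3, 3], 4.0),  # log2(8+8)
            ([10, 12], np.log2(2**10 + 2**12)),  # 12.321928...
        ],
    )
    def test_known_values(self, values, expected):
        assert log_sum(values) == pytest.approx(expected, abs=1e-12)

    def test_missing_ignored_and_all_missing_nan(self):
        assert log_sum([3, np.nan, 3]) == pytest.approx(4.0)
        assert np.isnan(log_sum([np.nan, np.nan]))


class TestMedianPolish:
    def test_single_feature_identity(self):
        m = pd.DataFrame([[1.0, 2.5, np.nan, 4.0]])
        out = median_polish_summarize(m)
        assert out.tolist() == [1.0, 2.5, 4.0]

    def test_constant_matrix(self):
        m = pd.DataFrame(np.full((4, 5), 3.25))
        out = median_polish_summarize(m)
        assert np.allclose(out, 3.25)

    def test_outlier_matrix_matches_reference_iteration(self):
        # 3x3 with one gross outlier; expected effects frozen from an
        # independent step-by-step median-polish iteration (cross-checked
        # against R stats::medpolish at eps=1e-10)
        m = np.array(
            [
                [10.0, 10.2, 9.9],
                [10.1, 15.0, 10.0],
                [9.8, 10.1, 10.05],
            ]
        )
        fit = median_polish(m, max_iter=20, tol=1e-10)
        assert fit.overall == pytest.approx(10.0, abs=1e-9)
        assert fit.col_effects == pytest.approx([0.0, 0.2, -0.1], abs=1e-9)
        assert fit.row_effects == pytest.approx([0.0, 0.1, -0.1], abs=1e-9)
        # the outlier cell is absorbed by the residual, not the summaries
        summaries = fit.overall + fit.col_effects
        assert summaries == pytest.approx([10.0, 10.2, 9.9], abs=1e-9)

    def test_agrees_with_log_sum_on_single_feature(self):
        m = pd.DataFrame([[5.5, 6.5]])
        mp = median_polish_summarize(m)
        ls = summarize.log_sum_summarize(m)
        pd.testing.assert_series_equal(mp, ls)

    @given(
        st.floats(min_value=-5, max_value=5),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=25, deadline=None)
    def test_location_equivariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(20, 1, (4, 6))
        m[rng.random((4, 6)) < 0.2] = np.nan
        base = median_polish_summarize(pd.DataFrame(m))
        shifted = median_polish_summarize(pd.DataFrame(m + shift))
        assert np.allclose(shifted - base, shift, atol=1e-9)


class TestRatioSummarize:
    def test_symmetry_and_k1_case(self):
        assert ratio_summarize([4.0, 7.0], [4.0, 7.0]) == pytest.approx(0.0)
        assert ratio_summarize([3.7], [1.2]) == pytest.approx(3.7 - 1.2)

    def test_derived_example(self):
        assert ratio_summarize([3, 3], [2]) == pytest.approx(2.0)

    def test_one_sided_missing_gives_nan(self):
        assert np.isnan(ratio_summarize([np.nan], [2.0]))

    def test_equals_difference_of_log_sums(self):
        mod, unmod = [3.1, 4.2, np.nan], [2.0, 2.5]
        assert ratio_summarize(mod, unmod) == pytest.approx(
            log_sum(mod) - log_sum(unmod)
        )

    def test_invariant_under_joint_shift(self):
        mod, unmod = [3.1, 4.2], [2.0, 2.5]
        base = ratio_summarize(mod, unmod)
        shifted = ratio_summarize([v + 1.7 for v in mod], [v + 1.7 for v in unmod])
        assert shifted == pytest.approx(base, abs=1e-9)


class TestGroupTargets:
    def test_single_and_multi_site_stay_separate(self):
        table = _mini_table(
            [
                ("P1", "S70", "AS*K", True),
                ("P1", "S70+T81", "AS*T*K", True),
                ("P1", None, "GGK", False),
            ]
        )
        groups = summarize.group_targets(table)
        assert set(groups) == {
            ("site", "P1", "S70"),
            ("site", "P1", "S70+T81"),
            ("protein", "P1"),
        }

    def test_unmodified_only_protein_target(self):
        table = _mini_table([("P9", None, "GGK", False)])
        assert set(summarize.group_targets(table)) == {("protein", "P9")}

    def test_empty(self):
        table = _mini_table([]).iloc[0:0]
        assert summarize.group_targets(table) == {}


class TestImputeAFT:
    def test_no_missing_unchanged(self):
        m = pd.DataFrame(np.arange(12.0).reshape(3, 4) + 10)
        pd.testing.assert_frame_equal(impute_aft(m), m)

    def test_disabled_is_noop(self):
        m = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        pd.testing.assert_frame_equal(impute_aft(m, enabled=False), m)

    def test_censored_model_recovery_beats_constant_minimum(self):
        # simulate from the censored two-way model and compare imputation
        # error against constant-minimum imputation (Monte-Carlo oracle)
        rng = np.random.default_rng(42)
        nrow, ncol = 10, 6
        row = rng.normal(0, 1.5, nrow)
        col = rng.normal(0, 0.5, ncol)
        truth = 20.0 + row[:, None] + col[None, :] + rng.normal(0, 0.4, (nrow, ncol))
        # left-censor each feature at its 30th generating percentile
        bound = np.quantile(truth, 0.3, axis=1, keepdims=True)
        observed = np.where(truth >= bound, truth, np.nan)
        m = pd.DataFrame(observed)
        imputed = impute_aft(m).to_numpy()
        miss = ~np.isfinite(observed)
        assert miss.any()
        obs_min = np.nanmin(observed, axis=1)
        # imputations respect the censoring bound
        assert (imputed[miss] <= np.broadcast_to(obs_min[:, None], miss.shape)[miss] + 1e-9).all()
        mae_model = np.abs(imputed[miss] - truth[miss]).mean()
        const = np.broadcast_to(obs_min[:, None], truth.shape)
        mae_const = np.abs(const[miss] - truth[miss]).mean()
        assert mae_model < mae_const

    def test_fully_missing_run_left_missing(self):
        m = pd.DataFrame([[10.0, np.nan], [11.0, np.nan]])
        with pytest.warns(UserWarning):
            out = impute_aft(m)
        assert out.iloc[:, 1].isna().all()


class TestSummarizeRuns:
    def test_median_polish_and_log_sum_columns(self, small_sim):
        enriched, _, _ = small_sim
        mp = summarize.summarize_runs(enriched, method="median_polish")
        assert list(mp.columns) == summarize.SUMMARY_COLUMNS
        assert (mp["method"] == "median_polish").all()
        assert mp["value"].notna().all()
        # one summary per (target, run)
        assert not mp.duplicated(["protein_id", "site_id", "run_id", "channel"]).any()

    def test_shift_equivariance_through_pipeline(self, small_sim):
        enriched, _, _ = small_sim
        base = summarize.summarize_runs(enriched, method="median_polish")
        shifted_tbl = enriched.assign(log2_intensity=enriched["log2_intensity"] + 2.0)
        shifted = summarize.summarize_runs(shifted_tbl, method="median_polish")
        assert np.allclose(shifted["value"] - base["value"], 2.0, atol=1e-9)

    def test_ratio_summaries_loss_accounting(self, small_sim):
        enriched, global_, _ = small_sim
        # knock out all modified features of one run to force a one-sided loss
        run = enriched["run_id"].iloc[0]
        knocked = enriched.copy()
        knocked.loc[knocked["run_id"] == run, "log2_intensity"] = np.nan
        ptm = summarize.summarize_runs(knocked, method="log_sum")
        prot = summarize.summarize_runs(global_, method="log_sum")
        ratios, loss = summarize.ratio_summaries(ptm, prot)
        n_targets = ptm[["protein_id", "site_id"]].drop_duplicates().shape[0]
        assert loss["protein_discarded"] == n_targets  # one lost run per protein
        assert loss["protein_discard_fraction"] == pytest.approx(
            n_targets / loss["protein_summaries"]
        )
        # uij equals the difference of the two log-sum summaries
        merged = ratios.merge(
            ptm, on=["protein_id", "run_id"], suffixes=("", "_ptm")
        ).merge(prot, on=["protein_id", "run_id"], suffixes=("", "_prot"))
        assert np.allclose(
            merged["value"], merged["value_ptm"] - merged["value_prot"], atol=1e-9
        )


def _mini_table(rows):
    data = {
        "protein_id": [],
        "site_id": [],
        "peptide": [],
        "charge": [],
        "feature_id": [],
        "run_id": [],
        "condition": [],
        "mixture_id": [],
        "channel": [],
        "replicate_id": [],
        "log2_intensity": [],
        "is_modified": [],
        "origin": [],
    }
    for protein, site, pep, modified in rows:
        data["protein_id"].append(protein)
        data["site_id"].append(site)
        data["peptide"].append(pep)
        data["charge"].append(2)
        data["feature_id"].append(f"{pep}/2")
        data["run_id"].append("R1")
        data["condition"].append("C1")
        data["mixture_id"].append(np.nan)
        data["channel"].append(np.nan)
        data["replicate_id"].append("B1")
        data["log2_intensity"].append(10.0)
        data["is_modified"].append(modified)
        data["origin"].append("enriched" if modified else "global")
    return pd.DataFrame(data)
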