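import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_summaries
from ptmquant import modeling
from ptmquant.modeling import (
    estimate_contrast,
    fit_oneway,
    fit_tmt_mixed,
    fit_variance_prior,
    moderate_variance,
)


class TestFitOneway:
    def test_hand_least_squares_example(self):
        summ = make_summaries({"C1": [1.0, 1.2], "C2": [2.0, 2.4]})
        fit = fit_oneway(summ)
        assert fit.condition_means == pytest.approx({"C1": 1.1, "C2": 2.2})
        assert fit.resid_var == pytest.approx(0.05)
        assert fit.resid_df == 2  # I(J-1) with I=2, J=2
        res = estimate_contrast(fit, ("C2", "C1"))
        assert res.estimate == pytest.approx(1.1)
        assert res.se == pytest.approx(np.sqrt(0.05))
        rev = estimate_contrast(fit, ("C1", "C2"))
        assert rev.estimate == pytest.approx(-1.1)
        assert rev.se == res.se and rev.pvalue == res.pvalue

    def test_constant_data_zero_variance(self):
        summ = make_summaries({"C1": [2.0, 2.0], "C2": [2.0, 2.0, 2.0]})
        fit = fit_oneway(summ)
        assert all(v == 2.0 for v in fit.condition_means.values())
        assert fit.resid_var == pytest.approx(0.0)
        res = estimate_contrast(fit, ("C2", "C1"))
        assert res.pvalue == 1.0  # zero estimate, zero variance

    @pytest.mark.parametrize("n_cond,n_rep", [(2, 3), (3, 4), (4, 2)])
    def test_balanced_residual_df(self, n_cond, n_rep):
        rng = np.random.default_rng(0)
        summ = make_summaries(
            {f"C{i}": rng.normal(size=n_rep).tolist() for i in range(n_cond)}
        )
        assert fit_oneway(summ).resid_df == n_cond * (n_rep - 1)

    def test_all_singleton_inestimable(self):
        summ = make_summaries({"C1": [1.0], "C2": [2.0]})
        fit = fit_oneway(summ)
        assert not fit.estimable
        res = estimate_contrast(fit, ("C2", "C1"))
        assert res.issue == "inestimable"
        assert np.isnan(res.pvalue)

    def test_absent_condition_flagged(self):
        summ = make_summaries({"C1": [1.0, 1.5]})
        res = estimate_contrast(fit_oneway(summ), ("C2", "C1"))
        assert res.issue == "single_condition"

    def test_agrees_with_pooled_t_test_oracle(self):
        # textbook two-sample pooled-variance t-test on 100 random balanced
        # datasets: estimates, SEs and p-values to 1e-10
        rng = np.random.default_rng(123)
        for _ in range(100):
            j = rng.integers(2, 8)
            a = rng.normal(0, 1, j)
            b = rng.normal(0.5, 1, j)
            summ = make_summaries({"C1": a.tolist(), "C2": b.tolist()})
            res = estimate_contrast(fit_oneway(summ), ("C2", "C1"))
            t, p = stats.ttest_ind(b, a, equal_var=True)
            assert res.estimate == pytest.approx(b.mean() - a.mean(), abs=1e-10)
            assert res.tstat == pytest.approx(t, abs=1e-10)
            assert res.pvalue == pytest.approx(p, abs=1e-10)


class TestFitTmtMixed:
    def _mixed_summaries(self, rng, n_mix=4, j_per=2, s2m=0.5, s2=0.2, delta=1.0):
        rows = {}
        mixtures = []
        vals_c1, vals_c2 = [], []
        for m in range(n_mix):
            b = rng.normal(0, np.sqrt(s2m))
            for _ in range(j_per):
                vals_c1.append(b + rng.normal(0, np.sqrt(s2)))
                vals_c2.append(delta + b + rng.normal(0, np.sqrt(s2)))
                mixtures.append(f"M{m}")
        summ = make_summaries({"C1": vals_c1, "C2": vals_c2})
        # interleave mixture labels per condition in generation order
        summ["mixture_id"] = summ["mixture_id"].astype(object)
        summ.loc[summ["condition"] == "C1", "mixture_id"] = mixtures
        summ.loc[summ["condition"] == "C2", "mixture_id"] = mixtures
        return summ

    def test_zero_mixture_variance_reproduces_oneway(self):
        rng = np.random.default_rng(5)
        summ = self._mixed_summaries(rng, s2m=0.0)
        mixed = fit_tmt_mixed(summ)
        ow = fit_oneway(summ)
        assert mixed.design == "tmt_mixed"
        assert mixed.mixture_var == pytest.approx(0.0, abs=0.05)
        for c in ow.condition_means:
            assert mixed.condition_means[c] == pytest.approx(
                ow.condition_means[c], abs=0.02
            )

    def test_single_mixture_falls_back_exactly(self):
        rng = np.random.default_rng(6)
        summ = make_summaries({"C1": rng.normal(size=4), "C2": rng.normal(size=4)})
        summ["mixture_id"] = "M0"
        mixed = fit_tmt_mixed(summ)
        ow = fit_oneway(summ)
        assert mixed.design == "fallback_oneway"
        assert mixed.condition_means == ow.condition_means
        assert mixed.resid_var == ow.resid_var

    def test_variance_component_recovery(self):
        # many balanced mixtures: REML should recover both components
        # within Monte-Carlo error of the method-of-moments ANOVA estimates
        rng = np.random.default_rng(7)
        summ = self._mixed_summaries(rng, n_mix=40, j_per=3, s2m=0.5, s2=0.2)
        fit = fit_tmt_mixed(summ)
        # method-of-moments from mixture means: var(mean_m) = s2m + s2/n_m
        per_mix = summ.groupby("mixture_id")["value"].agg(["mean", "var", "size"])
        resid = summ.groupby(["mixture_id", "condition"])["value"].var().mean()
        assert fit.resid_var == pytest.approx(0.2, abs=0.1)
        assert fit.mixture_var == pytest.approx(0.5, rel=0.5)
        mom_s2m = per_mix["mean"].var() - fit.resid_var / per_mix["size"].mean()
        assert fit.mixture_var == pytest.approx(mom_s2m, abs=0.15)

    def test_cross_check_against_statsmodels_mixedlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        summ = self._mixed_summaries(rng, n_mix=6, j_per=2, s2m=0.4, s2=0.3)
        fit = fit_tmt_mixed(summ)
        exog = pd.get_dummies(summ["condition"]).astype(float)
        ml = sm.MixedLM(summ["value"], exog, groups=summ["mixture_id"]).fit(reml=True)
        for i, c in enumerate(sorted(summ["condition"].unique())):
            assert fit.condition_means[c] == pytest.approx(ml.fe_params.iloc[i], abs=1e-4)
        assert fit.resid_var == pytest.approx(ml.scale, rel=1e-3)
        assert fit.mixture_var == pytest.approx(float(ml.cov_re.iloc[0, 0]), rel=1e-2)

    def test_balanced_satterthwaite_matches_closed_form(self):
        # fully balanced randomized block: the contrast eliminates the
        # mixture effect, so the ANOVA df is (I-1)(M-1)
        rng = np.random.default_rng(9)
        summ = self._mixed_summaries(rng, n_mix=6, j_per=1, s2m=0.6, s2=0.2)
        fit = fit_tmt_mixed(summ)
        res = estimate_contrast(fit, ("C2", "C1"))
        n, i_cond, m = 12, 2, 6
        closed = (i_cond - 1) * (m - 1)
        assert res.df == pytest.approx(closed, rel=0.35)
        assert res.df <= n - i_cond

    def test_unbalanced_allocation_still_estimates(self):
        rng = np.random.default_rng(10)
        summ = self._mixed_summaries(rng, n_mix=3, j_per=2)
        # condition C2 observed in only one mixture
        summ = summ[
            (summ["condition"] == "C1") | (summ["mixture_id"] == "M0")
        ].reset_index(drop=True)
        fit = fit_tmt_mixed(summ)
        res = estimate_contrast(fit, ("C2", "C1"))
        assert np.isfinite(res.estimate) and np.isfinite(res.pvalue)
        assert res.df <= fit.n_runs - 2


class TestModerateVariance:
    def _fits(self, s2_list, df=4):
        return [
            modeling.ModelFit(
                ("site", f"P{i}", "S1"), "oneway_fixed", {"C1": 0.0}, {"C1": df + 1},
                s2, float(df),
            )
            for i, s2 in enumerate(s2_list)
        ]

    def test_identical_variances_collapse_to_common_value(self):
        fits = moderate_variance(self._fits([0.3] * 10))
        assert all(f.resid_var == pytest.approx(0.3) for f in fits)
        assert all(np.isinf(f.resid_df) for f in fits)

    def test_shrinkage_toward_prior_and_df_gain(self):
        rng = np.random.default_rng(11)
        s2 = 0.3 * rng.chisquare(4, 200) / 4
        fits = moderate_variance(self._fits(s2.tolist()))
        raw_spread = np.std(s2)
        mod_spread = np.std([f.resid_var for f in fits])
        assert mod_spread < raw_spread
        assert all(f.resid_df > 4 for f in fits)

    def test_monotone_map_of_raw_variances(self):
        rng = np.random.default_rng(12)
        s2 = np.sort(0.2 * rng.chisquare(5, 50) / 5)
        fits = moderate_variance(self._fits(s2.tolist(), df=5))
        mod = [f.resid_var for f in fits]
        assert all(a <= b + 1e-12 for a, b in zip(mod, mod[1:]))

    def test_hyperparameter_recovery(self):
        # variances drawn from the scaled inverse-chi-square prior
        # (d0=4, s0^2=0.3) observed through chi2_4 sampling noise
        rng = np.random.default_rng(13)
        d0, s0sq, df, n = 4.0, 0.3, 4.0, 2000
        true_var = d0 * s0sq / rng.chisquare(d0, n)
        s2 = true_var * rng.chisquare(df, n) / df
        d0_hat, s0_hat = fit_variance_prior(s2, np.full(n, df))
        assert d0_hat == pytest.approx(d0, rel=0.15)
        assert s0_hat == pytest.approx(s0sq, rel=0.15)

    def test_limma_vs_anova_pvalue_direction(self):
        # moderation shrinks extreme variances: p-values drop for targets
        # shrunk downward and rise for targets shrunk upward
        rng = np.random.default_rng(14)
        s2 = 0.3 * rng.chisquare(4, 100) / 4
        fits = self._fits(s2.tolist())
        for f in fits:
            f.condition_means = {"C1": 0.0, "C2": 0.5}
            f.condition_counts = {"C1": 3, "C2": 3}
        moderated = moderate_variance(fits)
        for raw, mod in zip(fits, moderated):
            p_raw = estimate_contrast(raw, ("C2", "C1")).pvalue
            p_mod = estimate_contrast(mod, ("C2", "C1")).pvalue
            if mod.resid_var < raw.resid_var:
                assert p_mod <= p_raw + 1e-12
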