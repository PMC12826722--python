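import numpy as np
import pandas as pd
import pytest
from scipy import stats

import egaclock as eg
from egaclock.exposures import aic_from_rss


def fit_oracle(y, X):
    """Normal-equations OLS with textbook CI and overall F-test."""
    Xc = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.inv(Xc.T @ Xc) @ Xc.T @ y
    resid = y - Xc @ beta
    n, k = Xc.shape
    s2 = resid @ resid / (n - k)
    se = np.sqrt(np.diag(s2 * np.linalg.inv(Xc.T @ Xc)))
    tq = stats.t.ppf(0.975, n - k)
    rss = resid @ resid
    tss = np.sum((y - y.mean()) ** 2)
    f = ((tss - rss) / (k - 1)) / (rss / (n - k))
    f_p = stats.f.sf(f, k - 1, n - k)
    return beta, beta - tq * se, beta + tq * se, f_p


class TestSingleExposure:
    def test_binary_equals_group_mean_difference(self):
        rng = np.random.default_rng(0)
        x = pd.Series(pd.Categorical(rng.choice(["No", "Yes"], 80), categories=["No", "Yes"]))
        y = pd.Series(rng.normal(274, 11, 80))
        res = eg.fit_exposure_model(y, x, "GA", "binary")
        diff = y[x == "Yes"].mean() - y[x == "No"].mean()
        assert res.iloc[0]["coefficient"] == pytest.approx(diff, abs=1e-10)
        # F = t^2 for a single binary term
        t = stats.ttest_ind(y[x == "Yes"], y[x == "No"], equal_var=True).statistic
        f_from_p = stats.f.isf(res.iloc[0]["f_p"], 1, 78)
        assert f_from_p == pytest.approx(t**2, abs=1e-8)

    def test_toy_fixture_matches_matrix_oracle(self):
        y = pd.Series([270.0, 281, 268, 290, 275, 266, 284, 278])
        x = pd.Series([1.2, 3.4, 0.5, 5.0, 2.2, 0.1, 4.4, 3.0])
        res = eg.fit_exposure_model(y, x, "GA", "cont")
        beta, lo, hi, f_p = fit_oracle(y.to_numpy(), x.to_numpy()[:, None])
        row = res.iloc[0]
        assert row["coefficient"] == pytest.approx(beta[1], abs=1e-10)
        assert row["ci_low"] == pytest.approx(lo[1], abs=1e-10)
        assert row["ci_high"] == pytest.approx(hi[1], abs=1e-10)
        assert row["f_p"] == pytest.approx(f_p, abs=1e-10)

    def test_categorical_reference_from_declared_order(self):
        x = pd.Series(
            pd.Categorical(
                ["Vaginal", "Planned", "Vaginal", "Unplanned", "Planned", "Vaginal"],
                categories=["Vaginal", "Planned", "Unplanned"],
            )
        )
        y = pd.Series([274.0, 270, 276, 277, 269, 275])
        res = eg.fit_exposure_model(y, x, "GA", "delivery")
        assert list(res["level"]) == ["Planned", "Unplanned"]
        assert (res["reference"] == "Vaginal").all()

    def test_constant_exposure_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            eg.fit_exposure_model(
                pd.Series([1.0, 2, 3, 4]), pd.Series(["a"] * 4), "GA", "const"
            )

    def test_null_f_pvalues_uniform(self):
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(300):
            y = pd.Series(rng.normal(size=40))
            x = pd.Series(rng.normal(size=40))
            pvals.append(eg.fit_exposure_model(y, x, "GA", "x").iloc[0]["f_p"])
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 300)


class TestRunAllExposures:
    def test_q_within_outcome(self, small_cohort):
        _, ds, _, exposures, _ = small_cohort
        ga = ds.samples["ga_days"]
        outcomes = pd.DataFrame({"GA": ga.to_numpy(), "EGAA": np.random.default_rng(0).normal(0, 1, len(ga))})
        res = eg.run_all_exposures(outcomes, exposures)
        assert set(res["outcome"]) == {"GA", "EGAA"}
        for _, block in res.groupby("outcome"):
            term_p = block.groupby("exposure")["f_p"].first()
            np.testing.assert_allclose(
                block.groupby("exposure")["q"].first().to_numpy(),
                eg.bh_fdr(term_p.to_numpy()),
            )

    def test_degenerate_outcome_rejected(self, small_cohort):
        _, ds, _, exposures, _ = small_cohort
        outcomes = pd.DataFrame({"EGAA": np.zeros(len(exposures))})
        with pytest.raises(ValueError, match="degenerate"):
            eg.run_all_exposures(outcomes, exposures)


class TestBackwardSelection:
    def _noise_candidates(self, n, rng):
        return pd.DataFrame({f"noise{i}": rng.normal(size=n) for i in range(10)})

    def test_strong_predictor_retained(self):
        rng = np.random.default_rng(0)
        n = 300
        X = self._noise_candidates(n, rng)
        X["strong"] = rng.normal(size=n)
        y = pd.Series(5.0 * X["strong"] + rng.normal(size=n))  # effect = 5 noise SD
        sel = eg.backward_select_aic(y, X)
        assert "strong" in sel.retained_exposures

    def test_aic_trace_matches_rss_oracle(self):
        rng = np.random.default_rng(1)
        n = 120
        X = self._noise_candidates(n, rng).iloc[:, :5]
        X["strong"] = rng.normal(size=n)
        y = pd.Series(3.0 * X["strong"] + rng.normal(size=n))
        sel = eg.backward_select_aic(y, X)
        # replay the trace: refit each step's model independently
        remaining = list(X.columns)
        for step, dropped, aic in sel.aic_trace:
            if dropped != "<start>":
                remaining.remove(dropped)
            M = np.column_stack([np.ones(n)] + [X[t].to_numpy() for t in remaining])
            beta = np.linalg.lstsq(M, y.to_numpy(), rcond=None)[0]
            rss = float(np.sum((y.to_numpy() - M @ beta) ** 2))
            assert aic == pytest.approx(aic_from_rss(rss, n, M.shape[1]), abs=1e-8)

    def test_final_aic_never_above_full(self):
        rng = np.random.default_rng(2)
        X = self._noise_candidates(150, rng)
        y = pd.Series(rng.normal(size=150))
        sel = eg.backward_select_aic(y, X)
        aics = [a for _, _, a in sel.aic_trace]
        assert aics[-1] <= aics[0]
        assert all(b <= a + 1e-12 for a, b in zip(aics, aics[1:]))

    def test_categorical_dropped_as_block(self):
        rng = np.random.default_rng(3)
        n = 200
        X = pd.DataFrame(
            {
                "cat": pd.Categorical(rng.choice(list("abc"), n)),
                "strong": rng.normal(size=n),
            }
        )
        y = pd.Series(4.0 * X["strong"] + rng.normal(size=n))
        sel = eg.backward_select_aic(y, X)
        labels = [k for k in sel.coefficients if k.startswith("cat[")]
        # the categorical either survives whole or vanishes whole
        assert len(labels) in (0, 2)

    def test_overparameterized_rejected(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({f"x{i}": rng.normal(size=8) for i in range(10)})
        with pytest.raises(ValueError):
            eg.backward_select_aic(pd.Series(rng.normal(size=8)), X)

    def test_single_and_multi_estimates_agree_for_orthogonal_exposure(self):
        rng = np.random.default_rng(5)
        n = 400
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = pd.Series(2.0 * X["a"] + rng.normal(size=n))
        single = eg.fit_exposure_model(y, X["a"], "GA", "a").iloc[0]
        sel = eg.backward_select_aic(y, X)
        se = (single["ci_high"] - single["ci_low"]) / (2 * 1.96)
        assert abs(sel.coefficients["a"] - single["coefficient"]) < 2 * se

    def test_weak_signal_outcome_explains_less(self):
        """The multi-exposure fit explains far less variance for a noisy
        acceleration-like outcome than for the underlying strong outcome."""
        rng = np.random.default_rng(6)
        n = 300
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        strong = pd.Series(3.0 * X["a"] + rng.normal(size=n))
        weak = pd.Series(0.2 * X["a"] + rng.normal(size=n))
        r2_strong = eg.backward_select_aic(strong, X).adj_r2
        r2_weak = eg.backward_select_aic(weak, X).adj_r2
        assert r2_weak < r2_strong
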