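import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fasym
from fasym.lmm import (
    MODEL_SUITE,
    FAMixedModel,
    ModelSpec,
    _blocks,
    build_design,
    holm_adjust,
    satterthwaite_df,
)

DEMOG = ("age", "sex", "decade_of_birth")


class TestFit:
    def test_noise_free_scores_interpolated_exactly(self):
        """With zero residual and zero matriline variance, the generating
        coefficients are recovered exactly."""
        md = fasym.simulate_metadata(80, seed=2)
        md["fa_score"] = (
            0.01 + 2e-4 * md["age_at_death"] + 3e-3 * (md["sex"] == "M")
        )
        res = fasym.fit_lmm(md, spec=ModelSpec("exact", ("age", "sex"), "all"))
        assert res.params["Intercept"] == pytest.approx(0.01, abs=1e-8)
        assert res.params["age"] == pytest.approx(2e-4, abs=1e-8)
        assert res.params["sex[T.M]"] == pytest.approx(3e-3, abs=1e-8)
        assert res.sigma_resid2 == 0.0

    def test_zero_matriline_variance_matches_ols(self):
        df = fasym.simulate_scores(n=150, seed=0, sigma_matriline=0.0)
        model = FAMixedModel(df, ModelSpec("m", DEMOG, "all"))
        res = model.fit()
        assert res.boundary  # REML puts the matriline variance at the boundary
        X = model.design.to_numpy(float)
        ols = np.linalg.lstsq(X, model.endog, rcond=None)[0]
        np.testing.assert_allclose(res.params.to_numpy(), ols, atol=1e-6)

    def test_estimates_invariant_to_relabeling_and_row_order(self):
        df = fasym.simulate_scores(n=120, seed=7, sigma_matriline=0.002)
        spec = MODEL_SUITE[0]
        base = fasym.fit_lmm(df, spec=spec)
        scrambled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        scrambled["matriline"] = "lineage_" + scrambled["matriline"].str.upper()
        alt = fasym.fit_lmm(scrambled, spec=spec)
        np.testing.assert_allclose(
            base.params.to_numpy(), alt.params.to_numpy(), rtol=1e-6
        )
        np.testing.assert_allclose(base.df.to_numpy(), alt.df.to_numpy(), rtol=1e-4)

    def test_tvalue_identity(self):
        df = fasym.simulate_scores(n=100, seed=5, sigma_matriline=0.002)
        res = fasym.fit_lmm(df, spec=MODEL_SUITE[0])
        np.testing.assert_allclose(
            res.tvalues.to_numpy(),
            res.params.to_numpy() / res.bse.to_numpy(),
            rtol=1e-9,
        )

    def test_single_level_categorical_named_in_error(self):
        df = fasym.simulate_scores(n=100, seed=3)
        bad = ModelSpec("bad", ("age", "hurricane_yn"), "never_exposed")
        with pytest.raises(ValueError, match="hurricane_yn"):
            fasym.fit_lmm(df, spec=bad)

    def test_too_few_observations_rejected(self):
        df = fasym.simulate_scores(n=100, seed=3).head(4)
        df = df.assign(matriline=["a", "b", "a", "b"])
        with pytest.raises(ValueError, match="identify"):
            fasym.fit_lmm(df, spec=ModelSpec("m", DEMOG, "all"))

    def test_residual_df_fallback_flag(self):
        df = fasym.simulate_scores(n=100, seed=5, sigma_matriline=0.002)
        res = fasym.fit_lmm(df, spec=MODEL_SUITE[0], df_method="residual")
        k = len(res.params)
        assert (res.df == res.n_obs - k).all()
        assert res.df_method == "residual"


class TestSatterthwaite:
    def test_balanced_one_way_matches_between_group_df(self):
        """Closed-form oracle: intercept df in a balanced random-intercept
        design equals the between-group degrees of freedom g - 1."""
        rng = np.random.default_rng(0)
        g, m = 8, 6
        groups = np.repeat(np.arange(g), m)
        y = rng.normal(0, 1, g * m) + np.repeat(rng.normal(0, 2, g), m)
        X = np.ones((g * m, 1))
        resh = y.reshape(g, m)
        msb = m * ((resh.mean(1) - y.mean()) ** 2).sum() / (g - 1)
        msw = ((resh - resh.mean(1, keepdims=True)) ** 2).sum() / (g * (m - 1))
        theta = np.array([max(0.0, (msb - msw) / m), msw])
        df = satterthwaite_df(theta, _blocks(X, y, groups), np.array([1.0]))
        assert df == pytest.approx(g - 1, rel=1e-4)

    def test_matches_lmerTest_reference(self, tmp_path):
        """Estimates, SEs, Satterthwaite dfs and p-values agree with R's
        lmerTest on the identical data."""
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        df = fasym.simulate_scores(
            n=100, seed=3, beta={"male": 0.002, "hurricane": 0.003},
            sigma_matriline=0.002,
        )
        csv = tmp_path / "scores.csv"
        df.to_csv(csv, index=False)
        rcode = f"""
        suppressMessages(library(lmerTest))
        d <- read.csv("{csv}")
        d$decade_idx <- (d$decade_of_birth - 1950)/10
        m <- lmer(fa_score ~ age_at_death + sex + decade_idx +
                  hurricane_experienced + (1|matriline), data=d, REML=TRUE)
        co <- summary(m)$coefficients
        write.csv(co, "{tmp_path / 'ref.csv'}")
        """
        subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True,
                       timeout=300)
        ref = pd.read_csv(tmp_path / "ref.csv", index_col=0)
        res = fasym.fit_lmm(df, spec=MODEL_SUITE[0])
        order = ["Intercept", "age", "sex[T.M]", "decade_of_birth",
                 "hurricane_yn[T.True]"]
        np.testing.assert_allclose(
            res.params[order].to_numpy(), ref["Estimate"].to_numpy(), rtol=1e-5
        )
        np.testing.assert_allclose(
            res.bse[order].to_numpy(), ref["Std. Error"].to_numpy(), rtol=1e-5
        )
        np.testing.assert_allclose(
            res.df[order].to_numpy(), ref["df"].to_numpy(), atol=0.05
        )
        np.testing.assert_allclose(
            res.pvalues[order].to_numpy(), ref["Pr(>|t|)"].to_numpy(), atol=1e-6
        )


class TestModelSuite:
    def test_subset_sizes_mirror_study_structure(self):
        df = fasym.simulate_scores(n=275, seed=1)
        suite = fasym.run_model_suite(df)
        assert suite["model1_all_hurricane_yn"].n_obs == 275
        assert suite["model2_never_exposed"].n_obs == 174
        assert suite["model3_all_n_hurricanes"].n_obs == 275
        assert suite["model4_exposed_age_at_hurricane"].n_obs == 101

    def test_model_terms(self):
        df = fasym.simulate_scores(n=275, seed=1)
        suite = fasym.run_model_suite(df)
        assert "hurricane_yn[T.True]" in suite["model1_all_hurricane_yn"].params
        assert not any(
            "hurricane" in t for t in suite["model2_never_exposed"].params.index
        )
        m3 = suite["model3_all_n_hurricanes"].params.index
        assert {"n_hurricanes[T.1]", "n_hurricanes[T.2]"} <= set(m3)
        m4 = suite["model4_exposed_age_at_hurricane"].params.index
        assert {"age_at_hurricane[T.juvenile]", "age_at_hurricane[T.adult]"} <= set(m4)

    def test_two_hurricane_models_share_design_columns(self):
        df = fasym.simulate_scores(n=80, seed=4)
        d = build_design(df, ("age", "sex", "decade_of_birth", "hurricane_yn"))
        assert list(d.columns) == [
            "Intercept", "age", "sex[T.M]", "decade_of_birth",
            "hurricane_yn[T.True]",
        ]


class TestPosthoc:
    def test_holm_arithmetic(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04]
        )

    @given(
        st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=8)
    )
    def test_holm_closed_form(self, ps):
        """adjusted_(i) = max_{j<=i} min(1, (m-j+1) p_(j)) on sorted p."""
        adj = holm_adjust(ps)
        m = len(ps)
        order = np.argsort(ps)
        running = 0.0
        expected = np.empty(m)
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * ps[idx]))
            expected[idx] = running
        np.testing.assert_allclose(adj, expected, rtol=1e-12)
        assert (adj >= np.asarray(ps) - 1e-15).all()

    def test_shifted_level_drives_its_contrasts(self):
        df = fasym.simulate_scores(
            n=275, seed=6, beta={"adult": 0.05},
            sigma_matriline=0.0005, sigma_residual=0.003,
        )
        res = fasym.fit_lmm(df, spec=MODEL_SUITE[3])
        con = fasym.posthoc_holm(res, "age_at_hurricane").set_index("contrast")
        assert con.loc["fetal - adult", "adjusted_p"] < 0.05
        assert con.loc["juvenile - adult", "adjusted_p"] < 0.05
        assert con.loc["fetal - juvenile", "adjusted_p"] > 0.05

    def test_absent_factor_rejected(self):
        df = fasym.simulate_scores(n=100, seed=3)
        res = fasym.fit_lmm(df, spec=MODEL_SUITE[0])
        with pytest.raises(ValueError, match="age_at_hurricane"):
            fasym.posthoc_holm(res, "age_at_hurricane")

    def test_contrast_monotone_adjustment(self):
        df = fasym.simulate_scores(n=150, seed=9)
        res = fasym.fit_lmm(df, spec=MODEL_SUITE[3])
        con = fasym.posthoc_holm(res, "age_at_hurricane")
        assert (con["adjusted_p"] >= con["raw_p"] - 1e-15).all()


class TestPower:
    def test_null_saturation_and_monotonicity(self):
        """Power ~ alpha at zero effect, ~1 at a saturating effect, and
        non-decreasing across the grid (up to Monte-Carlo noise)."""
        md = fasym.simulate_metadata(80, seed=12)
        pr = fasym.power_simulation(
            md, effect_grid=(0.0, 10.0, 400.0), n_sims=120, alpha=0.05, seed=4
        )
        se = 2 * np.sqrt(0.05 * 0.95 / pr.n_sims)
        assert pr.power[0] == pytest.approx(0.05, abs=se + 0.02)
        assert pr.power[2] >= 0.97
        slack = 2 * np.sqrt(0.25 / pr.n_sims)
        assert pr.power[0] <= pr.power[1] + slack
        assert pr.power[1] <= pr.power[2] + slack
        assert pr.smallest_detectable(0.8) == 400.0

    def test_dataframe_shape(self):
        md = fasym.simulate_metadata(60, seed=1)
        pr = fasym.power_simulation(md, effect_grid=(0.0,), n_sims=5, seed=0)
        out = pr.to_dataframe()
        assert list(out.columns) == ["effect_pct", "power", "mc_se"]
        assert len(out) == 1
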