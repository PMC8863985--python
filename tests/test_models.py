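"""Mixed-model estimation, z-scoring, slope models and their comparisons."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from babytract.models import (LMMSpec, TractLMM, compare_random_slope,
                              correlate_across_bundles, fit_lmm,
                              fit_mean_bundle_development,
                              fit_nodewise_development, fit_slope_models,
                              refit_excluding_node_range, simulate_slope_table,
                              subsample_every_kth, zscore_coords)


def longitudinal_table(rng, n_sub=10, slope=8.9e-4, intercept=0.46,
                       sub_sd=0.01, noise_sd=0.0, slope_sd=0.0):
    rows = []
    for s in range(n_sub):
        u = rng.normal(0, sub_sd)
        v = rng.normal(0, slope_sd) if slope_sd else 0.0
        for age in (10, 95, 190):
            rows.append((f"s{s:02d}", age,
                         intercept + (slope + v) * age + u
                         + rng.normal(0, noise_sd)))
    return pd.DataFrame(rows, columns=["subject", "age_days", "value"])


SPEC = LMMSpec("value", ("age_days",), "subject")


class TestFitLMM:
    def test_zero_noise_slope_exact(self, rng):
        df = longitudinal_table(rng)
        res = fit_lmm(df, SPEC)
        assert res.beta["age_days"] == pytest.approx(8.9e-4, abs=1e-8)
        assert res.converged

    def test_shared_intercept_collapses_group_variance(self, rng):
        df = longitudinal_table(rng, sub_sd=0.0, noise_sd=0.01)
        res = fit_lmm(df, SPEC)
        assert res.var_random_intercept < 0.2 * res.var_residual

    def test_slope_unbiased_monte_carlo(self, rng):
        ests = [fit_lmm(longitudinal_table(rng, noise_sd=0.01), SPEC)
                .beta["age_days"] for _ in range(60)]
        mc_se = np.std(ests) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 8.9e-4) < 3 * mc_se + 1e-12

    def test_matches_lme4_reference(self, rng, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        df = longitudinal_table(rng, n_sub=8, noise_sd=0.01)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        r = subprocess.run(
            ["Rscript", "-e",
             'suppressMessages(library(lme4));'
             f'd<-read.csv("{csv}");'
             'm<-lmer(value~age_days+(1|subject),data=d,REML=TRUE);'
             'cat(fixef(m), logLik(m), sep=",")'],
            capture_output=True, text=True, timeout=120)
        assert r.returncode == 0, r.stderr
        b0, b1, llf = (float(x) for x in r.stdout.split(","))
        res = fit_lmm(df, SPEC)
        assert res.beta["Intercept"] == pytest.approx(b0, abs=1e-6)
        assert res.beta["age_days"] == pytest.approx(b1, rel=1e-5)
        assert res.loglik == pytest.approx(llf, abs=1e-4)

    def test_reduces_to_ols_without_group_structure(self, rng):
        # pure-noise groups: fixed effects must match plain least squares
        df = longitudinal_table(rng, sub_sd=0.0, noise_sd=0.02)
        res = fit_lmm(df, SPEC)
        X = np.column_stack([np.ones(len(df)), df["age_days"]])
        ols = np.linalg.lstsq(X, df["value"], rcond=None)[0]
        assert np.allclose(res.beta.values, ols, atol=5e-4)

    def test_few_groups_rejected(self, rng):
        df = longitudinal_table(rng, n_sub=1)
        with pytest.raises(ValueError, match="groups"):
            TractLMM(df, SPEC)

    def test_singular_design_rejected(self, rng):
        df = longitudinal_table(rng)
        df["age_copy"] = df["age_days"]
        with pytest.raises(ValueError, match="singular"):
            fit_lmm(df, LMMSpec("value", ("age_days", "age_copy"), "subject"))

    def test_summary_mentions_terms(self, rng):
        s = fit_lmm(longitudinal_table(rng), SPEC).summary()
        assert "age_days" in s and "REML" in s and "R2" in s


class TestRandomSlopeLRT:
    def test_null_rejection_rate_near_alpha(self, rng):
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            df = longitudinal_table(rng, noise_sd=0.01, slope_sd=0.0)
            hits += compare_random_slope(df, SPEC).significant
        # binomial margin around alpha = 0.05 (boundary-constrained LRT is
        # conservative, so the observed rate sits at or below alpha)
        assert hits / n_rep <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_strong_random_slopes_detected(self, rng):
        df = longitudinal_table(rng, noise_sd=0.005, slope_sd=5e-4)
        assert compare_random_slope(df, SPEC).significant


class TestZScoring:
    def _map(self, rng, n=60):
        return pd.DataFrame({
            "bundle": np.repeat([f"b{i}" for i in range(6)], n // 6),
            "node": np.tile(np.arange(1, n // 6 + 1) * 10, 6),
            "x_abs": rng.uniform(5, 60, n), "y": rng.uniform(-60, 40, n),
            "z": rng.uniform(-40, 40, n), "slope": rng.normal(8e-4, 1e-4, n),
            "newborn_mean": rng.uniform(0.42, 0.55, n)})

    def test_outputs_standardised(self, rng):
        out = zscore_coords(self._map(rng))
        for c in ("zx", "zy", "zz"):
            assert abs(out[c].mean()) < 1e-12
            assert out[c].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_two_rows_give_plus_minus_inv_sqrt2(self):
        d = pd.DataFrame({"x_abs": [0.0, 1.0], "y": [0.0, 2.0],
                          "z": [1.0, 3.0]})
        out = zscore_coords(d)
        assert np.allclose(sorted(out["zx"]), [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_interaction_mean_is_scaled_correlation(self, rng):
        # with sample-SD z-scores, mean(zx*zy) = r * (n-1)/n exactly
        d = self._map(rng)
        out = zscore_coords(d)
        r = np.corrcoef(d["x_abs"], d["y"])[0, 1]
        n = len(d)
        assert out["zx_zy"].mean() == pytest.approx(r * (n - 1) / n, abs=1e-12)

    def test_zero_variance_coordinate_rejected(self, rng):
        d = self._map(rng)
        d["z"] = 5.0
        with pytest.raises(ValueError, match="variance"):
            zscore_coords(d)

    def test_equivalent_fit_after_reparameterisation(self, rng):
        # zero-noise: fitting raw coordinates or z-scored ones must give the
        # same fixed-effects predictions (linear reparameterisation)
        d = self._map(rng)
        d["slope"] = 1e-3 + 2e-4 * d["x_abs"] / 60 + 1e-4 * d["z"] / 40
        dz = zscore_coords(d)
        raw = fit_lmm(d, LMMSpec("slope", ("x_abs", "z"), "bundle"))
        zed = fit_lmm(dz, LMMSpec("slope", ("zx", "zz"), "bundle"))
        pred_raw = (raw.beta["Intercept"] + raw.beta["x_abs"] * d["x_abs"]
                    + raw.beta["z"] * d["z"])
        pred_z = (zed.beta["Intercept"] + zed.beta["zx"] * dz["zx"]
                  + zed.beta["zz"] * dz["zz"])
        assert np.allclose(pred_raw, pred_z, atol=1e-8)


class TestSubsampling:
    def _map(self):
        return pd.DataFrame({
            "bundle": np.repeat(["a", "b"], 100),
            "node": np.tile(np.arange(1, 101), 2),
            "slope": np.zeros(200)})

    def test_every_10th_keeps_nodes_10_to_100(self):
        out = subsample_every_kth(self._map(), 10)
        assert len(out) == 20
        assert sorted(out["node"].unique()) == [10, 20, 30, 40, 50,
                                                60, 70, 80, 90, 100]

    def test_k1_identity_and_k100_single_node(self):
        assert len(subsample_every_kth(self._map(), 1)) == 200
        out = subsample_every_kth(self._map(), 100)
        assert list(out["node"].unique()) == [100] and len(out) == 2


class TestCorrelation:
    def test_perfect_line_r2_one(self):
        x = np.arange(10.0)
        r2, p, slope = correlate_across_bundles(x, 3 * x + 1)
        assert r2 == pytest.approx(1.0) and p < 1e-10 and slope > 0

    def test_negative_line_r2_one_negative_slope(self):
        x = np.arange(10.0)
        r2, _, slope = correlate_across_bundles(x, -x)
        assert r2 == pytest.approx(1.0) and slope == pytest.approx(-1.0)

    def test_null_r2_expectation_matches_1_over_n_minus_1(self, rng):
        n = 24
        r2s = [correlate_across_bundles(rng.normal(size=n),
                                        rng.normal(size=n))[0]
               for _ in range(500)]
        # E[R^2] = 1/(n-1) under independence
        assert np.mean(r2s) == pytest.approx(1 / (n - 1), abs=3 * 0.06 / np.sqrt(500))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            correlate_across_bundles([1, 2], [3, 4])
        with pytest.raises(ValueError):
            correlate_across_bundles([1, 1, 1], [1, 2, 3])


@pytest.fixture(scope="module")
def coords():
    """Subsampled node coordinates/newborn values from the phantom layout."""
    from babytract.phantom import PhantomConfig, generate_phantom
    cfg = PhantomConfig(seed=5, streamlines_per_bundle=5, n_distractors=0,
                        make_md=False)
    ph = generate_phantom(cfg)
    t = ph.truth.node_truth.rename(columns={"newborn_r1": "newborn_mean"})
    return subsample_every_kth(t, 10)


class TestSlopeModels:
    def test_pure_speedup_generation_favors_model1(self, coords):
        betas = {"intercept": 2.3e-3, "newborn": -3e-3}
        d = simulate_slope_table(coords, betas, 2e-5, seed=41)
        cmp = fit_slope_models(d)
        assert cmp.model1.beta["newborn_mean"] < 0
        assert cmp.model1.pvalue["newborn_mean"] < 1e-6
        assert cmp.model2.r2_marginal < cmp.model1.r2_marginal

    def test_pure_spatial_generation_favors_model2(self, coords):
        betas = {"intercept": 8.9e-4, "zz": 1.68e-4, "zy": -1.1e-4,
                 "zy_zz": 1.05e-4}
        hits = 0
        for s in range(10):
            d = simulate_slope_table(coords, betas, 2e-5, seed=100 + s)
            cmp = fit_slope_models(d)
            assert cmp.model2.r2_marginal > cmp.model1.r2_marginal
            hits += not cmp.lrt_3_vs_2.significant
        assert hits >= 9  # model 3 should rarely beat model 2 under this null

    def test_combined_generation_needs_model3(self, coords):
        betas = {"intercept": 2.3e-3, "newborn": -3e-3, "zz": 1.68e-4,
                 "zy": -1.1e-4, "zy_zz": 1.05e-4}
        d = simulate_slope_table(coords, betas, 2e-5, seed=42)
        cmp = fit_slope_models(d)
        assert cmp.lrt_3_vs_2.significant
        assert cmp.model3.loglik >= cmp.model2.loglik  # nesting

    def test_recovery_within_ci_at_nominal_rate(self, coords):
        betas = {"intercept": 2.3e-3, "newborn": -3e-3, "zx": 4.19e-5,
                 "zy": -1.1e-4, "zz": 1.68e-4, "zx_zy": -4.74e-5,
                 "zy_zz": 1.05e-4}
        terms = {"newborn_mean": -3e-3, "zx": 4.19e-5, "zy": -1.1e-4,
                 "zz": 1.68e-4, "zx_zy": -4.74e-5, "zy_zz": 1.05e-4}
        n_rep, covered = 60, {t: 0 for t in terms}
        for s in range(n_rep):
            d = simulate_slope_table(coords, betas, 2e-5, seed=500 + s)
            m3 = fit_slope_models(d).model3
            ci = m3.conf_int()
            for t, true in terms.items():
                covered[t] += ci.loc[t, "lower"] <= true <= ci.loc[t, "upper"]
        for t, c in covered.items():
            assert c / n_rep >= 0.9, (t, c)

    def test_exclude_zero_nodes_matches_full_fit(self, coords):
        betas = {"intercept": 2.3e-3, "newborn": -3e-3, "zz": 1.68e-4}
        d = simulate_slope_table(coords, betas, 2e-5, seed=7)
        full = fit_slope_models(d)
        # rebuild an un-subsampled map so the exclusion helper can subsample
        again = refit_excluding_node_range(d, k=10, exclude_first=0,
                                           exclude_last=0)
        assert np.allclose(full.model3.beta, again.model3.beta, atol=1e-12)

    def test_exclude_all_nodes_rejected(self, coords):
        with pytest.raises(ValueError, match="excluded"):
            refit_excluding_node_range(coords.assign(slope=0.0),
                                       exclude_first=60, exclude_last=60)


class TestPipelineModels:
    def test_mean_bundle_slopes_match_truth(self, tiny_phantom,
                                            tiny_profile_table):
        dev = fit_mean_bundle_development(tiny_profile_table, "r1")
        truth = (tiny_phantom.truth.node_truth
                 .groupby("bundle")["slope_r1"].mean())
        assert len(dev) == 24
        merged = dev.set_index("bundle").join(truth)
        err = (merged["slope"] - merged["slope_r1"]).abs()
        # allowance: member samples spread ~2 mm across the tube, where the
        # spatial-gradient term shifts the true rate away from its
        # centerline value by up to ~2e-5 s^-1/day
        assert (err < 3 * merged["slope_se"] + 2e-5).all()
        assert (merged["r2_adjusted"] > 0.8).all()

    def test_md_slopes_all_negative(self, tiny_profile_table):
        dev = fit_mean_bundle_development(tiny_profile_table, "md")
        assert (dev["slope"] < 0).all()

    def test_single_timepoint_rejected(self, tiny_profile_table):
        nb = tiny_profile_table[tiny_profile_table["timepoint"] == "0m"]
        with pytest.raises(ValueError, match="timepoints"):
            fit_mean_bundle_development(nb, "r1")

    def test_nodewise_map_shape_and_slope_signs(self, tiny_profile_table):
        nodes = list(range(10, 101, 10))
        dev = fit_nodewise_development(tiny_profile_table, "r1", nodes=nodes)
        assert len(dev) == 24 * 10
        assert not dev["missing"].any()
        assert (dev["slope"] > 0).all()   # R1 increases everywhere
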