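import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from compocor.diagnostics import (
    bias_curves,
    bias_regression,
    dip_statistic,
    dip_test,
    meta_correlation,
    signature_score,
    variance_explained,
)
from compocor.normalize import normalize
from compocor.simulate import SimulationConfig, generate_dataset


class TestDipStatistic:
    def test_two_point_equal_mass_is_quarter(self):
        # nearest unimodal CDF must sit 0.25 away at one of the two atoms
        assert dip_statistic([0, 0, 1, 1]) == pytest.approx(0.25)

    def test_equally_spaced_sample_attains_floor(self):
        # a uniform grid is fitted exactly up to the 1/(2n) step resolution
        assert dip_statistic(np.arange(20)) == pytest.approx(1 / 40)

    def test_three_point_hand_case(self):
        # jumps 1/4, 1/2, 1/4: the middle atom is the mode; the flanking
        # atoms each force a distance of 1/8
        assert dip_statistic([0.0, 1.0, 1.0, 2.0]) == pytest.approx(0.125)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=150)
        d1 = dip_statistic(x)
        d2 = dip_statistic(-4.2 * x + 11.0)
        assert d1 == pytest.approx(d2, abs=1e-14)

    def test_requires_four_finite_values(self):
        with pytest.raises(ValueError):
            dip_statistic([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            dip_statistic([1.0, 2.0, np.nan, 3.0])

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds_hold_universally(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 200))
        kind = seed % 3
        if kind == 0:
            x = rng.normal(size=n)
        elif kind == 1:
            x = rng.integers(0, 4, size=n).astype(float)  # heavy ties
        else:
            x = np.concatenate([rng.normal(size=n), rng.normal(8, 1, size=n)])
        d = dip_statistic(x)
        assert 1 / (2 * len(x)) - 1e-12 <= d <= 0.25 + 1e-12

    def test_bimodal_exceeds_unimodal(self):
        rng = np.random.default_rng(1)
        uni = rng.normal(size=300)
        bi = np.concatenate([rng.normal(size=150), rng.normal(6, 1, 150)])
        assert dip_statistic(bi) > 3 * dip_statistic(uni)


class TestDipTest:
    def test_bimodal_mixture_detected(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(4, 1, 50)])
        res = dip_test(x, n_mc=500, seed=0)
        assert res.p_value < 0.05

    def test_unimodal_size(self):
        rng = np.random.default_rng(3)
        rejections = 0
        for _ in range(50):
            res = dip_test(rng.normal(size=100), n_mc=500, seed=0)
            rejections += res.p_value < 0.05
        assert rejections <= 5  # >= 90% non-rejections

    def test_p_floor_is_mc_resolution(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([np.zeros(50), np.ones(50)]) + rng.normal(0, 0.01, 100)
        res = dip_test(x, n_mc=200, seed=0)
        assert res.p_value >= 1 / 200

    def test_low_n_mc_warns(self):
        with pytest.warns(UserWarning):
            dip_test([0.1, 0.5, 0.6, 0.9], n_mc=50, seed=0)


@pytest.fixture(scope="module")
def artifact_dataset():
    cfg = SimulationConfig(
        n_cohorts=5,
        samples_per_cohort=100,
        mt_fraction_mean=[0.1, 0.2, 0.3, 0.45, 0.6],
        mt_fraction_cv=0.3,
        rho_mt_nu=0.0,
        seed=0,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="module")
def curves(artifact_dataset):
    cm, cat, _ = artifact_dataset
    return bias_curves(
        cm,
        cat["mtOXPHOS"],
        cat["nuOXPHOS"],
        methods=("tpm", "mrn", "tmm"),
        n_iterations=30,
        seed=1,
    )


class TestBiasCurves:
    def test_tpm_mito_random_declines_with_mt_fraction(self, curves):
        tpm = curves[curves["method"] == "tpm"].sort_values("mt_mean")
        vals = tpm["median_set_random"].to_numpy()
        assert vals[0] > vals[2] > vals[4]
        assert vals[4] < -0.1

    def test_mrn_tmm_mito_random_flat(self, curves):
        flat = curves[curves["method"].isin(["mrn", "tmm"])]
        assert flat["median_set_random"].abs().max() <= 0.05

    def test_tpm_random_random_grows_with_mt_fraction(self, curves):
        tpm = curves[curves["method"] == "tpm"].sort_values("mt_mean")
        rr = tpm["median_random_random"].to_numpy()
        assert rr[4] > rr[0]
        assert rr[4] > 0.05

    def test_empty_method_list_rejected(self, artifact_dataset):
        cm, cat, _ = artifact_dataset
        with pytest.raises(ValueError):
            bias_curves(cm, cat["mtOXPHOS"], cat["nuOXPHOS"], methods=())

    def test_dominant_gene_injection_inflates_tpm_random_random(self):
        from compocor.simulate import inject_dominant_genes

        cfg = SimulationConfig(
            n_cohorts=2,
            samples_per_cohort=80,
            mt_fraction_mean=0.05,
            mt_fraction_cv=0.2,
            seed=3,
        )
        cm, cat, _ = generate_dataset(cfg)
        dominant = cat["background"][:4]
        pool = cat["background"][4:]
        # scale the dominant block per sample with a noisy multiplier so its
        # share varies across samples, as haemoglobin content does in blood
        rng = np.random.default_rng(5)
        counts = cm.counts.copy()
        mult = rng.lognormal(0, 0.5, size=counts.shape[1])
        counts.loc[dominant] = (counts.loc[dominant] * mult).round().astype(int)
        from compocor.io import CountMatrix

        noisy = CountMatrix(counts, cm.annotation, cm.metadata)
        injected = inject_dominant_genes(noisy, dominant, share=0.408)
        base_curves = bias_curves(
            cm, cat["mtOXPHOS"], cat["nuOXPHOS"], methods=("tpm",),
            pool=pool, random_panel_size=80, n_iterations=20, seed=4,
        )
        inj_curves = bias_curves(
            injected, cat["mtOXPHOS"], cat["nuOXPHOS"], methods=("tpm",),
            pool=pool, random_panel_size=80, n_iterations=20, seed=4,
        )
        # removing the dominant genes from the denominator deflates it again
        excl_curves = bias_curves(
            injected, cat["mtOXPHOS"], cat["nuOXPHOS"], methods=("cpm_excl",),
            pool=pool, random_panel_size=80, n_iterations=20, seed=4,
        )
        assert (
            inj_curves["median_random_random"].mean()
            > base_curves["median_random_random"].mean()
        )
        assert (
            excl_curves["median_random_random"].mean()
            < inj_curves["median_random_random"].mean()
        )


class TestBiasRegression:
    def test_perfectly_linear_outcome_r2_one(self):
        df = pd.DataFrame(
            {
                "cohort": [f"c{i}" for i in range(6)],
                "method": "tpm",
                "mt_mean": np.linspace(0.1, 0.6, 6),
                "mt_cv": np.linspace(0.3, 0.2, 6),
            }
        )
        df["median_set_pair"] = 0.1 - 0.8 * df["mt_mean"]
        out = bias_regression(df)
        assert out["mean"]["r_squared"] == pytest.approx(1.0)
        assert out["mean"]["coefficients"]["mt_mean"] == pytest.approx(-0.8)

    def test_constant_outcome_zero_slopes(self):
        df = pd.DataFrame(
            {
                "cohort": [f"c{i}" for i in range(5)],
                "method": "tpm",
                "mt_mean": np.linspace(0.1, 0.5, 5),
                "mt_cv": 0.3,
                "median_set_pair": 0.2,
            }
        )
        out = bias_regression(df)
        assert out["mean"]["coefficients"]["mt_mean"] == pytest.approx(0.0, abs=1e-12)

    def test_synthetic_artifact_has_negative_significant_slope(self):
        cfg = SimulationConfig(
            n_cohorts=12,
            samples_per_cohort=60,
            mt_fraction_mean=list(np.linspace(0.08, 0.6, 12)),
            mt_fraction_cv=0.3,
            seed=6,
        )
        cm, cat, _ = generate_dataset(cfg)
        curves = bias_curves(
            cm, cat["mtOXPHOS"], cat["nuOXPHOS"], methods=("tpm",),
            n_iterations=10, seed=2,
        )
        out = bias_regression(curves, outcome="median_set_pair")
        assert out["mean"]["coefficients"]["mt_mean"] < 0
        assert out["mean"]["f_pvalue"] < 0.05

    def test_collinear_predictor_dropped(self):
        df = pd.DataFrame(
            {
                "cohort": [f"c{i}" for i in range(6)],
                "method": "tpm",
                "mt_mean": np.linspace(0.1, 0.6, 6),
                "mt_cv": 0.0,  # cv constant: mean x cv aliased with 0, cv with const
                "median_set_pair": np.linspace(0, -0.5, 6),
            }
        )
        out = bias_regression(df)
        assert "mt_cv" in out["mean+cv"]["dropped"]


class TestSignatureScore:
    def test_single_gene_signature_is_its_zscore(self):
        rng = np.random.default_rng(7)
        vals = pd.DataFrame(
            rng.lognormal(3, 1, size=(3, 20)),
            index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(20)],
        )
        score = signature_score(vals, ["b"])
        t = np.log2(vals.loc["b"] + 1)
        expect = (t - t.mean()) / t.std(ddof=0)
        np.testing.assert_allclose(score.scores.to_numpy(), expect, rtol=1e-9)

    def test_constant_gene_excluded_without_changing_scores(self):
        rng = np.random.default_rng(8)
        vals = pd.DataFrame(
            rng.lognormal(3, 1, size=(2, 15)),
            index=["a", "b"],
            columns=[f"s{i}" for i in range(15)],
        )
        vals.loc["const"] = 7.0
        s1 = signature_score(vals, ["a", "b"])
        s2 = signature_score(vals, ["a", "b", "const"])
        np.testing.assert_allclose(s1.scores, s2.scores)
        assert s2.n_genes_excluded == 1

    def test_planted_high_cohort_scores_highest(self):
        cfg = SimulationConfig(n_cohorts=3, samples_per_cohort=50, seed=9)
        cm, cat, _ = generate_dataset(cfg)
        sig = cat["background"][:10]
        counts = cm.counts.copy()
        boost = cm.metadata["cohort"] == "cohort02"
        counts.loc[sig, boost.to_numpy()] *= 4
        from compocor.io import CountMatrix

        boosted = CountMatrix(counts, cm.annotation, cm.metadata)
        norm = normalize(boosted, "mrn")
        score = signature_score(norm, sig)
        means = score.scores.groupby(cm.metadata["cohort"]).mean()
        assert means.idxmax() == "cohort02"

    def test_all_constant_signature_rejected(self):
        vals = pd.DataFrame(
            np.ones((2, 5)), index=["a", "b"], columns=[f"s{i}" for i in range(5)]
        )
        with pytest.raises(ValueError):
            signature_score(vals, ["a", "b"])


class TestMetaCorrelation:
    def test_outcome_equal_gene_ranks_first(self):
        rng = np.random.default_rng(10)
        expr = pd.DataFrame(
            rng.normal(size=(30, 8)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"c{i}" for i in range(8)],
        )
        outcome = expr.loc["g5"].copy()
        res = meta_correlation(expr, outcome, top_n=5)
        assert res.top[0] == "g5"
        assert res.per_gene.loc["g5", "rho"] == pytest.approx(1.0)

    def test_constant_gene_dropped_and_counted(self):
        rng = np.random.default_rng(11)
        expr = pd.DataFrame(
            rng.normal(size=(5, 6)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"c{i}" for i in range(6)],
        )
        expr.loc["g2"] = 1.0
        outcome = pd.Series(rng.normal(size=6), index=expr.columns)
        res = meta_correlation(expr, outcome, top_n=3)
        assert res.n_dropped_constant == 1
        assert "g2" not in res.per_gene.index

    def test_top_n_capped_with_warning(self):
        rng = np.random.default_rng(12)
        expr = pd.DataFrame(
            rng.normal(size=(5, 5)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"c{i}" for i in range(5)],
        )
        outcome = pd.Series(rng.normal(size=5), index=expr.columns)
        with pytest.warns(UserWarning):
            res = meta_correlation(expr, outcome, top_n=100)
        assert len(res.top) == 5

    def test_planted_driver_ranks_in_top_tail(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n_genes, n_cohorts = 200, 20
            expr = pd.DataFrame(
                rng.normal(size=(n_genes, n_cohorts)),
                index=[f"g{i}" for i in range(n_genes)],
                columns=[f"c{i}" for i in range(n_cohorts)],
            )
            outcome = pd.Series(rng.normal(size=n_cohorts), index=expr.columns)
            expr.loc["driver"] = outcome + 0.3 * rng.normal(size=n_cohorts)
            res = meta_correlation(expr, outcome, top_n=2)
            hits += "driver" in res.top
        assert hits >= 9


class TestVarianceExplained:
    def test_identity_predictor_r2_one(self):
        y = pd.Series(np.linspace(0, 1, 30))
        r2, p = variance_explained(y.copy(), y)
        assert r2 == pytest.approx(1.0)

    def test_orthogonal_predictor_r2_near_zero(self):
        rng = np.random.default_rng(13)
        y = pd.Series(rng.normal(size=500))
        x = pd.Series(rng.normal(size=500))
        x = x - (x @ y) / (y @ y) * y  # explicit orthogonalization
        r2, _ = variance_explained(x, y)
        assert r2 <= 0.02

    def test_planted_r2_recovered(self):
        rng = np.random.default_rng(14)
        n = 1000
        x = rng.normal(size=n)
        noise = rng.normal(size=n)
        y = x + noise  # R2 = var(x)/(var(x)+var(noise)) = 0.5
        r2, p = variance_explained(
            pd.Series(x), pd.Series(y)
        )
        assert abs(r2 - 0.5) < 0.05
        assert p < 1e-10

    def test_multi_predictor_joint_r2(self):
        rng = np.random.default_rng(15)
        n = 400
        X = pd.DataFrame(rng.normal(size=(n, 5)))
        y = X.sum(axis=1) + rng.normal(size=n)
        r2_joint, _ = variance_explained(X, y)
        r2_single, _ = variance_explained(X[0], y)
        assert r2_joint > r2_single

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            variance_explained(
                pd.Series(np.ones(10)), pd.Series(np.arange(10.0))
            )
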