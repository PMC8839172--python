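"""Trial-statistics tests: outliers, transforms, ANOVA with a hand-worked
oracle, effect sizes, contrast consistency, correlations, PCA, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from canopyphene import synthgen
from canopyphene.fieldstats import (
    apply_transform,
    cluster_genotypes,
    consistent_contrasts,
    correlate_traits,
    factorial_anova,
    generalized_eta_squared,
    inverse_transform,
    iqr_outliers,
    pairwise_effect_sizes,
    pca_traits,
)


class TestIqrOutliers:
    def test_single_extreme_flagged(self):
        flags = iqr_outliers(np.array([1.0, 2.0, 3.0, 4.0, 100.0]))
        assert flags.tolist() == [False, False, False, False, True]

    def test_symmetric_clean_data_no_flags(self):
        assert not iqr_outliers(np.array([1.0, 2.0, 3.0, 4.0, 5.0])).any()

    def test_matches_direct_quantile_oracle(self, rng):
        for _ in range(50):
            v = rng.normal(size=rng.integers(6, 30))
            q1, q3 = np.percentile(v, [25, 75])
            iqr = q3 - q1
            expected = (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)
            assert np.array_equal(iqr_outliers(v), expected)

    def test_small_group_skipped_with_warning(self):
        values = np.array([1.0, 2.0, 100.0, 1.0, 2.0, 3.0, 4.0, 100.0])
        groups = pd.Series(["a"] * 3 + ["b"] * 5)
        with pytest.warns(UserWarning, match="skipped"):
            flags = iqr_outliers(values, groups)
        assert not flags[:3].any()  # small group untouched
        assert flags[7]

    def test_grouped_flags_are_within_group(self):
        # 10 is extreme within group a but ordinary in group b
        values = np.array([1.0, 1.1, 0.9, 1.05, 10.0, 9.0, 11.0, 10.5, 9.5, 10.0])
        groups = pd.Series(["a"] * 5 + ["b"] * 5)
        flags = iqr_outliers(values, groups)
        assert flags[4] and not flags[5:].any()


class TestTransforms:
    def test_reciprocal_twice_is_identity(self, rng):
        v = rng.uniform(0.5, 2.0, 20)
        assert np.allclose(apply_transform(apply_transform(v, "reciprocal"),
                                           "reciprocal"), v)

    def test_log_values(self):
        assert np.allclose(apply_transform([1.0, np.e], "log"), [0.0, 1.0])

    def test_sqrt_roundtrip(self, rng):
        v = rng.uniform(0.1, 5.0, 30)
        assert np.allclose(inverse_transform(apply_transform(v, "sqrt"), "sqrt"),
                           v, atol=1e-12)

    def test_domain_violation_lists_records(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            apply_transform([1.0, -2.0], "sqrt")

    def test_unknown_transform_rejected(self):
        with pytest.raises(ValueError):
            apply_transform([1.0], "boxcox")


class TestFactorialAnova:
    @pytest.fixture()
    def toy_2x2(self):
        """Hand-worked balanced 2x2 with 2 replicates per cell.

        Cell values: A1B1 {1,3}, A1B2 {5,7}, A2B1 {2,4}, A2B2 {8,10}.
        By hand: SS_A = 8, SS_B = 50, SS_AB = 2, SS_resid = 8 (df 4),
        F_A = 4, F_B = 25, F_AB = 1.
        """
        rows = []
        data = {("A1", "B1"): [1, 3], ("A1", "B2"): [5, 7],
                ("A2", "B1"): [2, 4], ("A2", "B2"): [8, 10]}
        for (a, b), vals in data.items():
            for v in vals:
                rows.append({"fa": a, "fb": b, "y": float(v)})
        return pd.DataFrame(rows)

    def test_matches_hand_computed_sums_of_squares(self, toy_2x2):
        res = factorial_anova(toy_2x2, "y", ["fa", "fb"])
        assert res.balanced
        assert res.table.loc["fa", "sum_sq"] == pytest.approx(8.0)
        assert res.table.loc["fb", "sum_sq"] == pytest.approx(50.0)
        assert res.table.loc["fa:fb", "sum_sq"] == pytest.approx(2.0)
        assert res.table.loc["Residual", "sum_sq"] == pytest.approx(8.0)
        assert res.table.loc["fa", "F"] == pytest.approx(4.0)
        assert res.table.loc["fb", "F"] == pytest.approx(25.0)
        assert res.table.loc["fa:fb", "F"] == pytest.approx(1.0)

    def test_term_plus_residual_equals_total_ss(self, toy_2x2):
        res = factorial_anova(toy_2x2, "y", ["fa", "fb"])
        total = ((toy_2x2["y"] - toy_2x2["y"].mean()) ** 2).sum()
        assert res.table["sum_sq"].sum() == pytest.approx(total)
        assert res.table["df"].sum() == len(toy_2x2) - 1

    def test_constant_response_all_zero_ss(self, toy_2x2):
        toy = toy_2x2.assign(y=5.0)
        res = factorial_anova(toy, "y", ["fa", "fb"])
        assert res.table.loc[["fa", "fb", "fa:fb"], "sum_sq"].abs().max() < 1e-20

    def test_empty_cell_identified(self, toy_2x2):
        broken = toy_2x2[~((toy_2x2.fa == "A2") & (toy_2x2.fb == "B2"))]
        with pytest.raises(ValueError, match="A2"):
            factorial_anova(broken, "y", ["fa", "fb"])

    def test_record_order_invariance(self):
        table = synthgen.generate_trial(
            synthgen.TrialDesign(), synthgen.TrialTruth(rng_seed=2)
        )
        a = factorial_anova(table, "yield", ["treatment", "genotype"], block="block")
        shuffled = table.sample(frac=1.0, random_state=1)
        b = factorial_anova(shuffled, "yield", ["treatment", "genotype"],
                            block="block")
        pd.testing.assert_frame_equal(a.table, b.table, check_exact=False,
                                      atol=1e-10)

    def test_balanced_emm_equal_cell_means(self):
        """In the balanced trial the fitted cell predictions are cell means."""
        import statsmodels.formula.api as smf

        table = synthgen.generate_trial(
            synthgen.TrialDesign(), synthgen.TrialTruth(rng_seed=4)
        )
        model = smf.ols("Q('yield') ~ C(treatment) * C(genotype)", table).fit()
        pred = model.predict(table)
        cell = table.groupby(["treatment", "genotype"], observed=True)[
            "yield"
        ].transform("mean")
        assert np.allclose(pred, cell)


class TestGeneralizedEtaSquared:
    def test_zero_effect_term_is_zero(self):
        # identical replicate patterns in both fa levels -> fa exactly null
        rows = []
        for a in ("A1", "A2"):
            for b, base in (("B1", 1.0), ("B2", 3.0)):
                for eps in (-0.2, 0.0, 0.2):
                    rows.append({"fa": a, "fb": b, "y": base + eps})
        res = factorial_anova(pd.DataFrame(rows), "y", ["fa", "fb"])
        ges = generalized_eta_squared(res)
        assert ges["fa"] == pytest.approx(0.0, abs=1e-12)

    def test_single_factor_reduces_to_classical_eta_squared(self):
        df = pd.DataFrame({
            "fa": ["A"] * 5 + ["B"] * 5,
            "y": [1.0, 1.2, 0.9, 1.1, 1.0, 2.0, 2.1, 1.9, 2.2, 2.0],
        })
        res = factorial_anova(df, "y", ["fa"])
        ges = generalized_eta_squared(res)
        ss_a = res.table.loc["fa", "sum_sq"]
        total = res.table["sum_sq"].sum()
        assert ges["fa"] == pytest.approx(ss_a / total)

    def test_monotone_in_configured_effect_size(self):
        design = synthgen.TrialDesign()
        ges_vals = []
        for factor in (1.0, 0.9, 0.8, 0.7):
            vals = []
            for seed in range(20):
                truth = synthgen.TrialTruth(
                    treatment_effect=factor, residual_sd=0.3, rng_seed=seed
                )
                t = synthgen.generate_trial(design, truth)
                res = factorial_anova(t, "yield", ["treatment", "genotype"],
                                      block="block")
                vals.append(generalized_eta_squared(res)["treatment"])
            ges_vals.append(np.mean(vals))
        assert all(a < b for a, b in zip(ges_vals, ges_vals[1:]))

    def test_unknown_measured_factor_rejected(self, ):
        df = pd.DataFrame({"fa": ["A", "A", "B", "B"], "y": [1.0, 2.0, 3.0, 4.0]})
        res = factorial_anova(df, "y", ["fa"])
        with pytest.raises(ValueError, match="unknown"):
            generalized_eta_squared(res, measured_factors={"nope"})

    def test_measured_factor_enters_denominator(self):
        table = synthgen.generate_trial(
            synthgen.TrialDesign(),
            synthgen.TrialTruth(rng_seed=9,
                                genotype_effects=np.linspace(-0.3, 0.3, 10)),
        )
        res = factorial_anova(table, "yield", ["treatment", "genotype"])
        plain = generalized_eta_squared(res)["treatment"]
        with_measured = generalized_eta_squared(
            res, measured_factors={"genotype"}
        )["treatment"]
        assert with_measured < plain


class TestPairwiseEffectSizes:
    def test_equal_means_zero_d(self):
        df = pd.DataFrame({
            "genotype": ["g1", "g1", "g2", "g2"] * 2,
            "treatment": ["FI"] * 4 + ["RI"] * 4,
            "y": [1.0, 3.0, 2.0, 2.0] * 2,
        })
        out = pairwise_effect_sizes(df, "y", sd_pooled=1.0)
        assert np.allclose(out["d"], 0.0)

    def test_one_sd_separation_gives_unit_d(self):
        df = pd.DataFrame({
            "genotype": ["g1"] * 3 + ["g2"] * 3,
            "treatment": ["FI"] * 6,
            "y": [2.0, 2.0, 2.0, 3.0, 3.0, 3.0],
        })
        out = pairwise_effect_sizes(df, "y", sd_pooled=1.0)
        assert abs(out["d"].iloc[0]) == pytest.approx(1.0)

    def test_antisymmetry_under_pair_swap(self):
        table = synthgen.generate_trial(
            synthgen.TrialDesign(), synthgen.TrialTruth(rng_seed=3)
        )
        out = pairwise_effect_sizes(table, "yield", sd_pooled=0.3)
        means = table.groupby(["treatment", "genotype"], observed=True)[
            "yield"].mean()
        for _, row in out.iterrows():
            forward = (means[(row.treatment, row.a)]
                       - means[(row.treatment, row.b)]) / 0.3
            backward = (means[(row.treatment, row.b)]
                        - means[(row.treatment, row.a)]) / 0.3
            assert row.d == pytest.approx(forward)
            assert backward == pytest.approx(-row.d)

    def test_zero_sd_rejected(self):
        df = pd.DataFrame({"genotype": ["a", "b"], "treatment": ["FI", "FI"],
                           "y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            pairwise_effect_sizes(df, "y", sd_pooled=0.0)


class TestConsistentContrasts:
    @staticmethod
    def _table(d_values):
        return pd.DataFrame({
            "treatment": ["FI"] * len(d_values),
            "a": [f"g{i}" for i in range(len(d_values))],
            "b": [f"h{i}" for i in range(len(d_values))],
            "d": d_values,
        })

    def test_one_failing_repetition_excludes(self):
        tables = {1: self._table([1.2]), 2: self._table([1.3]),
                  3: self._table([0.9])}
        assert len(consistent_contrasts(tables)) == 0

    def test_all_passing_included(self):
        tables = {1: self._table([1.2]), 2: self._table([1.3]),
                  3: self._table([1.1])}
        assert len(consistent_contrasts(tables)) == 1

    def test_matches_brute_force_triple_loop(self, rng):
        n = 30
        reps = {r: self._table(rng.normal(0, 1.2, n)) for r in (1, 2, 3)}
        out = consistent_contrasts(reps, threshold=1.0)
        kept = set(zip(out["a"], out["b"]))
        expected = set()
        for i in range(n):
            if all(abs(reps[r]["d"].iloc[i]) > 1.0 for r in (1, 2, 3)):
                expected.add((reps[1]["a"].iloc[i], reps[1]["b"].iloc[i]))
        assert kept == expected

    def test_missing_contrast_raises(self):
        t1 = self._table([1.2, 1.4])
        t2 = self._table([1.2, 1.4]).iloc[:1]
        with pytest.raises(ValueError, match="missing"):
            consistent_contrasts({1: t1, 2: t2})


class TestCorrelateTraits:
    def test_perfectly_correlated_pair(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        out = correlate_traits(df)
        row = out.iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.significant

    def test_monotone_nonlinear_pair_uses_spearman_r1(self, rng):
        x = rng.uniform(0.1, 4.0, 40)
        df = pd.DataFrame({"a": x, "b": np.exp(3 * x)})  # heavily non-normal
        out = correlate_traits(df)
        row = out.iloc[0]
        assert row.method == "spearman"
        assert row.r == pytest.approx(1.0)

    def test_constant_trait_masked(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0], "b": [2.0] * 5})
        out = correlate_traits(df)
        assert out.iloc[0]["method"] == "undefined"
        assert not out.iloc[0]["significant"]


class TestPcaTraits:
    @pytest.fixture()
    def means(self, rng):
        return pd.DataFrame(
            rng.normal(size=(12, 5)),
            columns=[f"t{i}" for i in range(5)],
        )

    def test_variance_fractions_sum_to_one(self, means):
        _, _, var_frac = pca_traits(means)
        assert var_frac.sum() == pytest.approx(1.0, abs=1e-12)

    def test_duplicated_trait_loads_on_shared_direction(self, rng):
        x = rng.normal(size=20)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=20)})
        scores, loadings, var_frac = pca_traits(df)
        # the two duplicated traits load identically on PC1
        assert loadings.loc["a", "PC1"] == pytest.approx(loadings.loc["b", "PC1"])

    def test_full_reconstruction_identity(self, means):
        scores, loadings, _ = pca_traits(means)
        X = means.to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=0)
        recon = scores.to_numpy() @ loadings.to_numpy().T
        assert np.abs(recon - Z).max() < 1e-10

    def test_loadings_orthonormal(self, means):
        _, loadings, _ = pca_traits(means)
        L = loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_missing_cells_rejected(self, means):
        means.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            pca_traits(means)


class TestClusterGenotypes:
    def test_five_separated_blobs_ari_one(self, rng):
        centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10], [5, 20]])
        X, truth = [], []
        for k, c in enumerate(centers):
            X.append(c + rng.normal(0, 0.3, size=(6, 2)))
            truth += [k] * 6
        df = pd.DataFrame(np.vstack(X))
        labels, _ = cluster_genotypes(df, k=5)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equal_n_gives_singletons(self, rng):
        df = pd.DataFrame(rng.normal(size=(6, 3)))
        labels, _ = cluster_genotypes(df, k=6)
        assert labels.nunique() == 6

    def test_duplicate_rows_share_cluster(self, rng):
        base = rng.normal(size=(7, 3))
        df = pd.DataFrame(np.vstack([base, base[0]]))
        labels, _ = cluster_genotypes(df, k=3)
        assert labels.iloc[0] == labels.iloc[-1]

    def test_fewer_observations_than_k_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_genotypes(pd.DataFrame(rng.normal(size=(3, 2))), k=5)
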