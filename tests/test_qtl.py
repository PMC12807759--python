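import numpy as np
import pandas as pd
import pytest

from m6akit.qtl import (
    MLevelMatrix,
    compute_m_levels,
    define_cis_window,
    estimate_latent_factors,
    filter_missingness,
    gc_correct,
    ma_normalize,
    map_cis_qtl,
    natural_spline_basis,
    zscore_rows_then_quantile_columns,
)
from m6akit.simulate import simulate_qtl_cohort


class TestMLevels:
    def test_balanced_cell_is_zero(self):
        ip = np.array([[5.0], [45.0]])
        inp = np.array([[20.0], [180.0]])
        m = compute_m_levels(ip, inp)
        # IP 5/50 vs Input 20/200 -> log(0.1/0.1) = 0
        assert m.values[0, 0] == pytest.approx(0.0)

    def test_zero_coverage_missing(self):
        ip = np.array([[0.0, 3.0], [10.0, 4.0]])
        inp = np.array([[0.0, 2.0], [10.0, 4.0]])
        m = compute_m_levels(ip, inp)
        assert np.isnan(m.values[0, 0])
        assert np.isfinite(m.values[1, 0])

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        ip = rng.integers(1, 100, size=(30, 4)).astype(float)
        inp = rng.integers(1, 100, size=(30, 4)).astype(float)
        m = compute_m_levels(ip, inp)
        for i in range(30):
            for j in range(4):
                expected = np.log((ip[i, j] / ip[:, j].sum()) / (inp[i, j] / inp[:, j].sum()))
                assert m.values[i, j] == pytest.approx(expected, rel=1e-12)

    def test_pseudocount_on_one_sided_zero(self):
        ip = np.array([[0.0], [10.0]])
        inp = np.array([[5.0], [10.0]])
        m = compute_m_levels(ip, inp)
        assert np.isfinite(m.values[0, 0])

    def test_unpaired_shape_error(self):
        with pytest.raises(ValueError):
            compute_m_levels(np.zeros((3, 2)), np.zeros((3, 3)))


class TestMissingness:
    def test_row_thresholds_strict(self):
        vals = np.zeros((3, 10))
        vals[0, :3] = np.nan  # 30% -> removed
        vals[1, :2] = np.nan  # 20% -> kept (strict >)
        m = filter_missingness(MLevelMatrix(vals, ["a", "b", "c"], [f"s{j}" for j in range(10)]))
        assert m.site_ids == ["b", "c"]

    def test_no_missing_identity(self):
        vals = np.arange(12.0).reshape(3, 4)
        m = filter_missingness(MLevelMatrix(vals, list("abc"), list("wxyz")))
        np.testing.assert_array_equal(m.values, vals)

    def test_rows_then_columns_order(self):
        # adversarial: column 0 is >80% missing only before row filtering
        vals = np.ones((5, 2))
        vals[0:4, 0] = np.nan          # col0: 80% missing over all rows
        vals[0:4, 1] = np.nan          # same rows missing in col1 -> rows 0-3 removed first
        m = filter_missingness(MLevelMatrix(vals, list("abcde"), ["x", "y"]))
        # oracle: rows with >20% missing (rows 0-3) drop; remaining col missing = 0%
        assert m.site_ids == ["e"]
        assert m.sample_ids == ["x", "y"]

    def test_all_rows_removed_error(self):
        vals = np.full((2, 4), np.nan)
        with pytest.raises(ValueError):
            filter_missingness(MLevelMatrix(vals, ["a", "b"], list("wxyz")))


class TestMANormalize:
    def _mat(self, vals):
        return MLevelMatrix(np.asarray(vals, dtype=float),
                            [f"r{i}" for i in range(len(vals))],
                            [f"c{j}" for j in range(np.asarray(vals).shape[1])])

    def test_identical_samples_unchanged(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=50)
        vals = np.column_stack([col, col, col])
        out, _ = ma_normalize(self._mat(vals))
        np.testing.assert_allclose(out.values, vals, atol=1e-10)

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=100)
        c = 1.7
        vals = np.column_stack([base, base + c])
        out, state = ma_normalize(self._mat(vals))
        # closed-form OLS: slope 0, intercept c/1... reference is mean, offset symmetric
        np.testing.assert_allclose(out.values[:, 1] - out.values[:, 0], 0.0, atol=1e-8)

    def test_refit_slope_zero(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=200) * 2 + 1
        bias = 0.4 * base  # M' proportional to A'
        vals = np.column_stack([base, base + bias, base - bias])
        out, state = ma_normalize(self._mat(vals))
        slopes, intercepts = state.refit(out.values)
        assert np.max(np.abs(slopes)) < 1e-8
        assert np.max(np.abs(intercepts)) < 1e-8

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            ma_normalize(self._mat(np.ones((5, 1))))


class TestGCCorrect:
    def _mat(self, vals, gc):
        m = MLevelMatrix(np.asarray(vals, dtype=float),
                         [f"r{i}" for i in range(len(vals))],
                         [f"c{j}" for j in range(np.asarray(vals).shape[1])])
        m.gc = np.asarray(gc, dtype=float)
        return m

    def test_gc_independent_values_centered(self):
        rng = np.random.default_rng(4)
        n = 2000
        gc = rng.uniform(0.2, 0.8, n)
        vals = rng.normal(size=(n, 2))
        out = gc_correct(self._mat(vals, gc))
        centered = vals - vals.mean(axis=0)
        assert np.abs(out.values - centered).max() < 0.2  # spline fit of noise is ~flat
        assert abs(out.values[:, 0].mean()) < 1e-10

    def test_planted_quadratic_trend_removed(self):
        rng = np.random.default_rng(5)
        n = 2000
        gc = rng.uniform(0.2, 0.8, n)
        trend = 3.0 * (gc - 0.5) ** 2
        vals = np.column_stack([trend + rng.normal(0, 0.1, n)])
        out = gc_correct(self._mat(vals, gc))
        r = np.corrcoef(out.values[:, 0], gc)[0, 1]
        assert abs(r) < 0.02

    def test_constant_values_all_zero(self):
        gc = np.linspace(0.2, 0.8, 100)
        out = gc_correct(self._mat(np.full((100, 1), 2.5), gc))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_df_exceeds_distinct_error(self):
        with pytest.raises(ValueError):
            gc_correct(self._mat(np.ones((4, 1)), [0.1, 0.1, 0.2, 0.2]), df=4)

    def test_basis_shape(self):
        x = np.linspace(0, 1, 50)
        assert natural_spline_basis(x, df=4).shape == (50, 4)


class TestZscoreQuantile:
    def test_row_zscore(self):
        from m6akit.qtl import zscore_rows
        scaled, keep = zscore_rows(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(scaled[0], [-1.0, 0.0, 1.0])
        assert keep.all()

    def test_hand_quantile_example(self):
        from m6akit.qtl import _quantile_normalize_columns
        vals = np.array([[5.0, 4.0], [2.0, 1.0], [3.0, 4.0]])
        out = _quantile_normalize_columns(vals)
        np.testing.assert_allclose(out[:, 0], [4.5, 1.5, 3.5])
        np.testing.assert_allclose(out[:, 1], [4.0, 1.5, 4.0])

    def test_identical_columns_unchanged_by_quantile(self):
        from m6akit.qtl import _quantile_normalize_columns
        col = np.array([0.3, -1.2, 2.0, 0.0])
        vals = np.column_stack([col, col])
        np.testing.assert_allclose(_quantile_normalize_columns(vals), vals)

    def test_columns_share_sorted_multiset(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(50, 4)) * rng.uniform(0.5, 2, size=(50, 1))
        out = zscore_rows_then_quantile_columns(
            MLevelMatrix(vals, [f"r{i}" for i in range(50)], list("wxyz")))
        ref = np.sort(out.values[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out.values[:, j]), ref)

    def test_zero_variance_row_dropped(self):
        vals = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.warns(RuntimeWarning):
            out = zscore_rows_then_quantile_columns(
                MLevelMatrix(vals, ["a", "b"], ["x", "y", "z"]))
        assert out.site_ids == ["b"]


class TestLatentFactors:
    def test_planted_rank_one_detected(self):
        rng = np.random.default_rng(7)
        u = rng.normal(size=(200, 1))
        v = rng.normal(size=(1, 30))
        X = 5.0 * u @ v + rng.normal(size=(200, 30))
        factors = estimate_latent_factors(X, None, seed=0)
        assert factors.shape[1] >= 1

    def test_factors_orthonormal(self):
        rng = np.random.default_rng(8)
        X = 5.0 * rng.normal(size=(200, 2)) @ rng.normal(size=(2, 30)) + rng.normal(size=(200, 30))
        factors = estimate_latent_factors(X, None, seed=0)
        if factors.shape[1]:
            np.testing.assert_allclose(factors.T @ factors, np.eye(factors.shape[1]), atol=1e-10)

    def test_iid_noise_mostly_zero_factors(self):
        zeros = 0
        for s in range(10):
            rng = np.random.default_rng(200 + s)
            X = rng.normal(size=(100, 20))
            k = estimate_latent_factors(X, None, seed=s).shape[1]
            zeros += (k == 0)
        assert zeros >= 8


class TestCisWindow:
    def test_plus_strand_union(self):
        assert define_cis_window(10000, 15000, "+") == [(8000, 15000)]

    def test_minus_strand_reflection(self):
        # "-" gene with TSS at the right end 15000: promoter [14800, 17000]
        win = define_cis_window(10000, 15000, "-")
        assert win == [(10000, 17000)]
        promoter_only = define_cis_window(15000, 15000, "-")
        assert promoter_only == [(14800, 17000)]

    def test_clamped_to_chromosome(self):
        assert define_cis_window(1000, 1100, "+") == [(1, 1200)]
        assert define_cis_window(900, 1000, "-", chrom_length=1500) == [(800, 1500)]


class TestMapCisQtl:
    def test_null_calibration(self):
        fracs = []
        for s in range(10):
            c = simulate_qtl_cohort(n_samples=80, n_sites=20, effect_sd=0.0, seed=s)
            tab = map_cis_qtl(c["phenotypes"], c["genotypes"], c["variant_pos"], c["windows"],
                              covariates=c["covariates"], n_perm=200, seed=1000 + s)
            fracs.append((tab["empirical_p_direct"] < 0.05).mean())
        assert 0.01 <= np.mean(fracs) <= 0.10

    def test_planted_effect_power_and_sign(self):
        c = simulate_qtl_cohort(n_samples=100, n_sites=20, fixed_effect=1.0, seed=3)
        tab = map_cis_qtl(c["phenotypes"], c["genotypes"], c["variant_pos"], c["windows"],
                          covariates=c["covariates"], n_perm=200, seed=30)
        detected = tab[tab["empirical_p_direct"] < 0.05]
        assert len(detected) >= 18
        causal = c["truth"].data["causal"]
        signs = [np.sign(row["slope"]) == np.sign(causal[row["site_id"]]["effect"])
                 for _, row in detected.iterrows()]
        assert np.mean(signs) >= 0.95

    def test_beta_approx_close_to_direct(self):
        c = simulate_qtl_cohort(n_samples=80, n_sites=20, effect_sd=0.0, seed=5)
        tab = map_cis_qtl(c["phenotypes"], c["genotypes"], c["variant_pos"], c["windows"],
                          covariates=c["covariates"], n_perm=1000, seed=50)
        diff = (tab["empirical_p_beta"] - tab["empirical_p_direct"]).abs()
        assert diff.mean() < 0.02

    def test_monomorphic_excluded(self):
        c = simulate_qtl_cohort(n_samples=50, n_sites=2, effect_sd=0.0, seed=6)
        geno = c["genotypes"].copy()
        first = c["genotypes"].index[:29]
        geno.loc[first] = 1.0  # monomorphic
        tab = map_cis_qtl(c["phenotypes"], c["genotypes"], c["variant_pos"], c["windows"],
                          covariates=c["covariates"], n_perm=50, seed=60)
        tab2 = map_cis_qtl(c["phenotypes"], geno, c["variant_pos"], c["windows"],
                           covariates=c["covariates"], n_perm=50, seed=60)
        assert tab2["n_variants"].iloc[0] < tab["n_variants"].iloc[0]

    def test_missing_dosage_imputed(self):
        c = simulate_qtl_cohort(n_samples=50, n_sites=2, effect_sd=0.0, seed=7)
        geno = c["genotypes"].astype(float).copy()
        geno.iloc[0, 0] = np.nan
        tab = map_cis_qtl(c["phenotypes"], geno, c["variant_pos"], c["windows"],
                          covariates=c["covariates"], n_perm=50, seed=70)
        assert np.isfinite(tab["nominal_p"]).all()

    def test_misaligned_columns_error(self):
        c = simulate_qtl_cohort(n_samples=20, n_sites=2, effect_sd=0.0, seed=8)
        with pytest.raises(ValueError):
            map_cis_qtl(c["phenotypes"], c["genotypes"].iloc[:, ::-1], c["variant_pos"],
                        c["windows"], n_perm=10, seed=1)
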