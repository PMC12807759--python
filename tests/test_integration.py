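import numpy as np
import pytest

from m6akit import simulate
from m6akit.integration import (
    BetaProfile,
    IDRFit,
    aggregate_counts,
    compute_beta,
    differential_idr,
    fit_idr,
    is_orthogonal,
    pairwise_coverage_filter,
    validate_pair,
    validate_sites,
)
from m6akit.matrix import MethylationMatrix, SampleRecord


def copula_mixture_sample(rng, n, p, rho, mu, sigma):
    """Draw directly from the generative copula-mixture model."""
    signal = rng.random(n) < p
    cov = sigma**2 * np.array([[1, rho], [rho, 1]])
    z = np.empty((n, 2))
    if signal.any():
        z[signal] = rng.multivariate_normal([mu, mu], cov, size=int(signal.sum()))
    z[~signal] = rng.standard_normal((int((~signal).sum()), 2))
    return z[:, 0], z[:, 1], signal


class TestOrthogonality:
    def test_antibody_chemical_true(self):
        assert is_orthogonal("antibody", "chemical", "MeRIP-seq", "GLORI")

    def test_direct_antibody_false(self):
        assert not is_orthogonal("direct", "antibody", "ONT-DRS", "m6ACE-seq")
        assert not is_orthogonal("antibody", "direct")

    def test_same_category_false(self):
        assert not is_orthogonal("antibody", "antibody", "MeRIP-seq", "m6ACE-seq")

    def test_unknown_category(self):
        with pytest.raises(ValueError):
            is_orthogonal("antibody", "psychic")


class TestAggregate:
    def _matrix(self):
        samples = [
            SampleRecord("a", condition="baseline"),
            SampleRecord("b", condition="baseline"),
            SampleRecord("c", condition="KD", is_baseline=False),
            SampleRecord("iv", is_ivt=True),
        ]
        k = np.array([[3, 5, 7, 1], [0, 2, 1, 0]])
        n = np.array([[10, 20, 30, 5], [4, 6, 2, 1]])
        return MethylationMatrix(["s1", "s2"], samples, k, n)

    def test_two_sample_sum(self):
        m6a, total = aggregate_counts(self._matrix())
        assert m6a.tolist() == [8, 2]
        assert total.tolist() == [30, 10]

    def test_single_sample_identity(self):
        m6a, total = aggregate_counts(self._matrix(), baseline_only=False, condition="KD")
        assert m6a.tolist() == [7, 1]

    def test_excludes_ivt(self):
        m6a, _ = aggregate_counts(self._matrix(), baseline_only=False)
        assert m6a.tolist() == [15, 3]  # a+b+c, never iv

    def test_empty_selection(self):
        with pytest.raises(ValueError):
            aggregate_counts(self._matrix(), condition="missing")

    def test_loop_oracle(self):
        rng = np.random.default_rng(8)
        n = rng.integers(0, 50, size=(20, 4))
        k = rng.binomial(n, 0.3)
        m = MethylationMatrix([f"s{i}" for i in range(20)],
                              [SampleRecord(f"x{j}") for j in range(4)], k, n)
        m6a, total = aggregate_counts(m)
        for i in range(20):
            assert m6a[i] == sum(int(k[i, j]) for j in range(4))
            assert total[i] == sum(int(n[i, j]) for j in range(4))


class TestBeta:
    def test_formula(self):
        # m6A = 3, unmethylated A = 1 -> total = 4, beta = 0.75
        prof = compute_beta([3], [4], jitter_factor=0.0, seed=None)
        assert prof.beta[0] == 0.75

    def test_zero_total_missing(self):
        prof = compute_beta([0], [0], jitter_factor=0.0, seed=None)
        assert np.isnan(prof.beta[0])

    def test_jitter_breaks_ties(self):
        prof = compute_beta(np.full(100, 30), np.full(100, 60), jitter_factor=1e-4, seed=1)
        assert np.unique(prof.beta).size == 100
        np.testing.assert_allclose(prof.beta, 0.5, rtol=1.1e-4)

    def test_jitter_deterministic(self):
        a = compute_beta(np.arange(50), np.arange(50) + 10, seed=3)
        b = compute_beta(np.arange(50), np.arange(50) + 10, seed=3)
        np.testing.assert_array_equal(a.beta, b.beta)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            compute_beta([-1], [5])


class TestCoverageFilter:
    def test_boundary(self):
        idx = pairwise_coverage_filter([19, 20], [25, 20])
        assert idx.tolist() == [1]

    def test_set_builder_oracle(self):
        rng = np.random.default_rng(6)
        t1 = rng.integers(0, 50, 200)
        t2 = rng.integers(0, 50, 200)
        got = set(pairwise_coverage_filter(t1, t2).tolist())
        expected = {i for i in range(200) if t1[i] >= 20 and t2[i] >= 20}
        assert got == expected


class TestFitIDR:
    def test_model_recovery(self):
        rng = np.random.default_rng(7)
        x, y, signal = copula_mixture_sample(rng, 5000, 0.6, 0.9, 2.5, 0.8)
        fit = fit_idr(x, y)
        assert abs(fit.p - 0.6) < 0.05
        assert (fit.idr_global[signal] < 0.05).mean() >= 0.9

    def test_null_noise(self):
        rng = np.random.default_rng(11)
        with pytest.warns(RuntimeWarning):
            fit = fit_idr(rng.random(5000), rng.random(5000))
        assert (fit.idr_global < 0.05).mean() <= 0.01

    def test_rank_invariance_monotone_transform(self):
        rng = np.random.default_rng(12)
        x, y, _ = copula_mixture_sample(rng, 1000, 0.5, 0.8, 2.0, 1.0)
        a = fit_idr(x, y)
        b = fit_idr(np.exp(x), y)
        np.testing.assert_array_equal(a.idr_local, b.idr_local)
        np.testing.assert_array_equal(a.idr_global, b.idr_global)

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(13)
        x, y, _ = copula_mixture_sample(rng, 800, 0.5, 0.8, 2.0, 1.0)
        perm = rng.permutation(800)
        a = fit_idr(x, y)
        b = fit_idr(x[perm], y[perm])
        np.testing.assert_allclose(a.idr_local[perm], b.idr_local, atol=1e-10)

    def test_global_idr_monotone_in_local(self):
        rng = np.random.default_rng(14)
        x, y, _ = copula_mixture_sample(rng, 2000, 0.4, 0.7, 2.0, 1.0)
        fit = fit_idr(x, y)
        order = np.argsort(fit.idr_local)
        assert np.all(np.diff(fit.idr_global[order]) >= -1e-12)
        assert fit.idr_local.min() >= 0 and fit.idr_local.max() <= 1

    def test_too_few_sites(self):
        with pytest.raises(ValueError):
            fit_idr(np.arange(50), np.arange(50))

    def test_constant_margin_degenerate(self):
        with pytest.warns(RuntimeWarning):
            fit = fit_idr(np.ones(200), np.arange(200.0))
        assert fit.degenerate

    @pytest.mark.parametrize("p,rho", [(0.3, 0.6), (0.5, 0.9), (0.7, 0.6)])
    def test_grid_recovery(self, p, rho):
        errs_p, errs_r = [], []
        for s in range(3):
            rng = np.random.default_rng(900 + s)
            x, y, _ = copula_mixture_sample(rng, 5000, p, rho, 2.5, 0.8)
            fit = fit_idr(x, y)
            errs_p.append(abs(fit.p - p))
            errs_r.append(abs(fit.rho - rho))
        assert max(errs_p) < 0.07
        assert max(errs_r) < 0.1


class TestValidate:
    def _fit(self, idr_global):
        idr_global = np.asarray(idr_global, dtype=float)
        return IDRFit(2.0, 1.0, 0.8, 0.5, idr_global.copy(), idr_global)

    def test_three_criteria_conjunction(self):
        fit = self._fit([0.01, 0.01, 0.2])
        res = validate_sites(fit, [True, False, True], [True, True, True])
        assert res.validated.tolist() == [True, False, False]

    def test_index_mismatch(self):
        with pytest.raises(ValueError):
            validate_sites(self._fit([0.01]), [True, True], [True])

    def test_end_to_end_planted(self):
        (k1, n1), (k2, n2), truth = simulate.simulate_technique_pair(
            n_sites=1000, reproducible_fraction=0.1, depth1=150, depth2=150,
            depth_dispersion=0.1, seed=11)
        res, fit, keep = validate_pair(k1, n1, k2, n2, seed=5)
        planted = np.flatnonzero(truth.data["reproducible"])
        validated_idx = keep[res.validated]
        recall = np.isin(planted, validated_idx).mean()
        false_frac = (~truth.data["reproducible"][validated_idx]).mean() if validated_idx.size else 0.0
        assert recall >= 0.9
        assert false_frac <= 0.1


class TestDifferential:
    @staticmethod
    def _profiles(pair):
        k, n = pair
        return compute_beta(k, n, jitter_factor=0.0, seed=None)

    def test_planted_dm_recovered(self):
        tech1, tech2, truth = simulate.simulate_dm_pair(n_sites=1000, n_dm=100, delta=-0.5, seed=21)
        res = differential_idr(
            self._profiles(tech1["treated"]), self._profiles(tech1["control"]),
            self._profiles(tech2["treated"]), self._profiles(tech2["control"]), seed=3)
        dm = truth.data["dm"][res.index]
        recall = (res.validated & dm).sum() / dm.sum()
        assert recall >= 0.9

    def test_validated_have_larger_delta(self):
        tech1, tech2, truth = simulate.simulate_dm_pair(n_sites=1000, n_dm=100, delta=-0.5, seed=22)
        res = differential_idr(
            self._profiles(tech1["treated"]), self._profiles(tech1["control"]),
            self._profiles(tech2["treated"]), self._profiles(tech2["control"]), seed=4)
        mag = (np.abs(res.delta1) + np.abs(res.delta2)) / 2
        assert mag[res.validated].mean() > mag[~res.validated].mean()

    def test_identical_conditions_degenerate(self):
        n = np.full(300, 50)
        k = np.full(300, 10)
        prof = compute_beta(k, n, jitter_factor=0.0, seed=None)
        with pytest.warns(RuntimeWarning):
            res = differential_idr(prof, prof, prof, prof)
        assert res.degenerate
        assert not res.validated.any()

    def test_coverage_filter_on_all_four(self):
        n_hi = np.full(300, 50)
        n_lo = np.full(300, 5)
        k = np.minimum(10, n_lo)
        hi = compute_beta(k, n_hi, jitter_factor=0.0, seed=None)
        lo = compute_beta(k, n_lo, jitter_factor=0.0, seed=None)
        with pytest.raises(ValueError):
            differential_idr(hi, hi, hi, lo)
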