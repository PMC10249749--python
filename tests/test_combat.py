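"""ComBat core: standardization algebra, EB shrinkage, adjustment contracts."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from scipy import stats

from combatsim._errors import ValidationError
from combatsim.combat import (
    CombatFit,
    apply_adjustment,
    eb_hyperparameters,
    eb_posteriors,
    harmonize,
    standardize,
)
from combatsim.datasets import make_default_dataset


def brute_force_location_scale(Y, sites):
    """Independent per-feature EB-off oracle: explicit scalar-loop location-scale."""
    Y = np.asarray(Y, dtype=float)
    site_list = list(dict.fromkeys(sites))
    n, p = Y.shape
    out = np.empty_like(Y)
    for v in range(p):
        y = Y[:, v]
        means = {s: y[sites == s].mean() for s in site_list}
        ns = {s: (sites == s).sum() for s in site_list}
        alpha = sum(ns[s] * means[s] for s in site_list) / n
        sigma2 = sum((y[i] - means[sites[i]]) ** 2 for i in range(n)) / n
        sigma = np.sqrt(sigma2)
        z = (y - alpha) / sigma
        for s in site_list:
            zs = z[sites == s]
            gamma = zs.mean()
            delta = zs.std(ddof=1)
            out[sites == s, v] = sigma * (z[sites == s] - gamma) / delta + alpha
    return out


@pytest.fixture(scope="module")
def two_site_fixture():
    rng = np.random.default_rng(17)
    Y = np.vstack([
        rng.normal(10, 2, size=(40, 5)),
        rng.normal(13, 3, size=(60, 5)),
    ])
    sites = np.array(["a"] * 40 + ["b"] * 60, dtype=object)
    return Y, sites


class TestStandardize:
    def test_single_site_reduces_to_centering_scaling(self, rng):
        Y = rng.normal(5, 2, size=(50, 4))
        fit, Z = standardize(Y, np.array(["s"] * 50, dtype=object))
        np.testing.assert_allclose(fit.alpha_hat, Y.mean(axis=0), rtol=1e-12)
        np.testing.assert_allclose(fit.gamma_hat, 0.0, atol=1e-10)
        expected = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=0)
        np.testing.assert_allclose(Z, expected, rtol=1e-10)

    def test_two_equal_sites_closed_form(self, rng):
        # brute-force normal equations under the weighted sum-to-zero constraint
        n = 30
        Y = np.vstack([rng.normal(3, 1, size=(n, 3)), rng.normal(7, 1, size=(n, 3))])
        sites = np.array(["a"] * n + ["b"] * n, dtype=object)
        fit, Z = standardize(Y, sites)
        m1, m2 = Y[:n].mean(axis=0), Y[n:].mean(axis=0)
        np.testing.assert_allclose(fit.alpha_hat, (m1 + m2) / 2, rtol=1e-12)
        # constraint sum_i n_i gamma = 0 on the standardized scale
        np.testing.assert_allclose(
            (fit.site_sizes[:, None] * fit.gamma_hat).sum(axis=0), 0.0, atol=1e-8
        )
        # standardized site-a mean is (m1 - alpha)/sigma
        np.testing.assert_allclose(
            fit.gamma_hat[0], (m1 - (m1 + m2) / 2) / fit.sigma_hat, rtol=1e-8
        )

    def test_pooled_variance_is_unit(self, two_site_fixture):
        Y, sites = two_site_fixture
        fit, Z = standardize(Y, sites)
        resid_var = np.mean(Z**2, axis=0) - np.mean(Z, axis=0) ** 2
        # residual (within-site) variance pools to ~1 by construction
        within = np.vstack([Z[sites == s] - Z[sites == s].mean(axis=0) for s in ("a", "b")])
        np.testing.assert_allclose((within**2).mean(axis=0), 1.0, rtol=1e-10)
        del resid_var

    def test_pure_noise_covariate_barely_moves_intercept(self, rng):
        Y = np.vstack([rng.normal(0, 1, size=(400, 3)), rng.normal(1, 1, size=(400, 3))])
        sites = np.array(["a"] * 400 + ["b"] * 400, dtype=object)
        x = rng.normal(size=800)
        fit0, _ = standardize(Y, sites)
        fit1, _ = standardize(Y, sites, X=x)
        se = fit0.sigma_hat / np.sqrt(800)
        assert np.all(np.abs(fit1.alpha_hat - fit0.alpha_hat) < 4 * se)

    def test_collinear_covariate_rejected(self, two_site_fixture):
        Y, sites = two_site_fixture
        x = (sites == "a").astype(float)
        with pytest.raises(ValidationError):
            standardize(Y, sites, X=x)


class TestEBHyperparameters:
    def test_moment_inversion_mean2_var1(self):
        # {1, 2, 3} has mean 2 and variance 1 (ddof=1) -> lambda=6, theta=10;
        # sampling from InverseGamma(6, 10) indeed has mean 2 and variance 1
        fit = CombatFit(sites=["a"], gamma_hat=np.zeros((1, 3)),
                        delta_hat_sq=np.array([[1.0, 2.0, 3.0]]))
        fit = eb_hyperparameters(fit)
        assert fit.lam[0] == pytest.approx(6.0)
        assert fit.theta[0] == pytest.approx(10.0)
        rng = np.random.default_rng(3)
        d2 = stats.invgamma.rvs(6, scale=10, size=200_000, random_state=rng)
        assert d2.mean() == pytest.approx(2.0, rel=0.02)
        assert d2.var() == pytest.approx(1.0, rel=0.1)

    def test_constant_gamma_gives_zero_tau(self):
        fit = CombatFit(sites=["a"], gamma_hat=np.full((1, 5), 0.7),
                        delta_hat_sq=np.array([[1.0, 1.1, 0.9, 1.2, 0.8]]))
        fit = eb_hyperparameters(fit)
        assert fit.gamma_bar[0] == pytest.approx(0.7)
        assert fit.tau_sq[0] == 0.0

    def test_two_features_rejected(self):
        fit = CombatFit(sites=["a"], gamma_hat=np.zeros((1, 2)),
                        delta_hat_sq=np.ones((1, 2)))
        with pytest.raises(ValidationError):
            eb_hyperparameters(fit)

    def test_recovers_sampled_hyperpriors(self):
        # sampling from the implied inverse-gamma recovers the moment pair
        rng = np.random.default_rng(9)
        d2 = stats.invgamma.rvs(6, scale=10, size=(1, 50_000), random_state=rng)
        fit = CombatFit(sites=["a"], gamma_hat=rng.normal(0.5, 0.2, size=(1, 50_000)),
                        delta_hat_sq=d2)
        fit = eb_hyperparameters(fit)
        assert fit.gamma_bar[0] == pytest.approx(0.5, abs=0.01)
        assert fit.tau_sq[0] == pytest.approx(0.04, rel=0.05)
        assert fit.lam[0] == pytest.approx(6.0, rel=0.1)
        assert fit.theta[0] == pytest.approx(10.0, rel=0.12)


class TestEBPosteriors:
    def _fit_for(self, Z, sites):
        fit, Z2 = standardize(Z, sites)
        return eb_hyperparameters(fit), Z2

    def test_huge_tau_gives_no_shrinkage(self, two_site_fixture):
        Y, sites = two_site_fixture
        fit, Z = self._fit_for(Y, sites)
        fit.tau_sq = np.full(2, 1e12)
        fit = eb_posteriors(Z, sites, fit)
        np.testing.assert_allclose(fit.gamma_star, fit.gamma_hat, atol=1e-6)

    def test_zero_tau_gives_total_shrinkage(self, two_site_fixture):
        Y, sites = two_site_fixture
        fit, Z = self._fit_for(Y, sites)
        fit.tau_sq = np.zeros(2)
        fit = eb_posteriors(Z, sites, fit)
        for i in range(2):
            np.testing.assert_allclose(fit.gamma_star[i], fit.gamma_bar[i], atol=1e-12)

    def test_large_n_likelihood_dominates(self):
        ds = make_default_dataset(n_sites=2, n_per_site=10_000, n_features=20,
                                  target_idp=5, seed=21)
        fit, Z = standardize(ds.values, ds.site_labels)
        fit = eb_hyperparameters(fit)
        fit = eb_posteriors(Z, ds.site_labels, fit)
        assert np.abs(fit.gamma_star - fit.gamma_hat).max() < 0.05
        assert np.abs(fit.delta_star**2 - fit.delta_hat_sq).max() < 0.05
        assert fit.converged


class TestAdjustment:
    def test_identity_when_no_site_effects_estimated(self, two_site_fixture):
        Y, sites = two_site_fixture
        fit, Z = standardize(Y, sites)
        fit.gamma_star = np.zeros_like(fit.gamma_hat)
        fit.delta_star = np.ones_like(fit.gamma_hat)
        out = apply_adjustment(Z, sites, fit)
        np.testing.assert_allclose(out, Y, rtol=1e-10)

    def test_constant_shift_sites_equalized(self, rng):
        base = rng.normal(0, 1, size=(50, 4))
        Y = np.vstack([base, base + 2.5])
        sites = np.array(["a"] * 50 + ["b"] * 50, dtype=object)
        harmonized, _ = harmonize(Y, sites, eb=False)
        gap = harmonized[:50].mean(axis=0) - harmonized[50:].mean(axis=0)
        np.testing.assert_allclose(gap, 0.0, atol=1e-8)

    def test_within_site_correlation_invariance(self, reduced_dataset):
        ds = reduced_dataset
        harmonized, _ = harmonize(ds.values, ds.site_labels)
        for site in ds.sites:
            rows = ds.site_rows(site)
            for v in (0, 15, 29):
                r0 = stats.pearsonr(ds.values[rows, v], ds.behavior[rows]).statistic
                r1 = stats.pearsonr(harmonized[rows, v], ds.behavior[rows]).statistic
                assert abs(r0 - r1) < 1e-10
                s0 = stats.spearmanr(ds.values[rows, v], ds.behavior[rows]).statistic
                s1 = stats.spearmanr(harmonized[rows, v], ds.behavior[rows]).statistic
                assert s0 == s1


class TestHarmonize:
    def test_eb_off_matches_brute_force_oracle(self, two_site_fixture):
        Y, sites = two_site_fixture
        harmonized, _ = harmonize(Y, sites, eb=False)
        oracle = brute_force_location_scale(Y, sites)
        np.testing.assert_allclose(harmonized, oracle, atol=1e-10)

    def test_homogenization_of_generated_site_effects(self):
        ds = make_default_dataset(n_per_site=1000, n_features=20, target_idp=5, seed=31)
        harmonized, _ = harmonize(ds.values, ds.site_labels)
        s1, s2, s3 = (ds.site_rows(s) for s in ds.sites)
        gaps_before, gaps_after = [], []
        for a, b in ((s1, s2), (s1, s3), (s2, s3)):
            gaps_before.append(np.abs(ds.values[a].mean(0) - ds.values[b].mean(0)))
            gaps_after.append(np.abs(harmonized[a].mean(0) - harmonized[b].mean(0)))
            ratio = harmonized[a].var(0, ddof=1) / harmonized[b].var(0, ddof=1)
            assert np.all((ratio > 0.9) & (ratio < 1.1))
        assert np.mean(np.concatenate(gaps_after)) < 0.05 * np.mean(np.concatenate(gaps_before))

    def test_exact_idempotence_without_shrinkage(self, reduced_dataset):
        # with site effects fully removed (no EB) and the unbiased variance
        # denominator, a second pass is the identity
        ds = reduced_dataset
        once, _ = harmonize(ds.values, ds.site_labels, eb=False, ml_variance=False)
        twice, _ = harmonize(once, ds.site_labels, eb=False, ml_variance=False)
        pooled_sd = once.std()
        assert np.abs(twice - once).max() < 1e-6 * pooled_sd

    def test_near_idempotence_with_shrinkage(self, reduced_dataset):
        # EB re-estimates its priors on refit and re-shrinks the residual
        # site effects, so repetition contracts rather than fixes: the second
        # pass moves values by far less than the first
        ds = reduced_dataset
        once, _ = harmonize(ds.values, ds.site_labels)
        twice, _ = harmonize(once, ds.site_labels)
        first_move = np.abs(once - ds.values).mean()
        second_move = np.abs(twice - once).mean()
        assert second_move < 0.05 * first_move
        assert np.abs(twice - once).max() < 0.05 * once.std()

    def test_pseudo_sites_from_homogeneous_population(self, rng):
        # splitting one population into 3 pseudo-sites should barely change values
        ds = make_default_dataset(n_per_site=1000, n_features=15, target_idp=5,
                                  additive_shift_scale=0.0,
                                  multiplicative_scale_range=(1.0, 1.0), seed=41)
        harmonized, _ = harmonize(ds.values, ds.site_labels)
        pooled_sd = ds.values.std(axis=0).mean()
        assert np.abs(harmonized - ds.values).mean() < 0.05 * pooled_sd

    def test_all_false_exclude_mask_is_bit_identical(self, two_site_fixture):
        Y, sites = two_site_fixture
        plain, _ = harmonize(Y, sites)
        masked, _ = harmonize(Y, sites, exclude_mask=np.zeros(len(Y), dtype=bool))
        np.testing.assert_array_equal(plain, masked)

    def test_robust_mode_preserves_contaminated_site_variance(self):
        from combatsim.outliers import OutlierSpec, Scenario, inject_outliers
        from combatsim.evaluation import normal_sample_moments

        ds = make_default_dataset(n_per_site=300, n_features=30, target_idp=15, seed=51)
        spec = OutlierSpec(Scenario.ONE_SITE_UNILATERAL, 0.05, 20.0, seed=52)
        inj = inject_outliers(ds, spec, target_idp=15)
        naive, _ = harmonize(inj.values, inj.site_labels)
        robust, _ = harmonize(inj.values, inj.site_labels, exclude_mask=inj.outlier_rows)
        clean, _ = harmonize(ds.values, ds.site_labels)
        var_clean = clean[ds.site_rows("Site 1"), 15].var(ddof=1)
        var_robust = normal_sample_moments(inj, 15, values=robust).loc["Site 1", "var"]
        var_naive = normal_sample_moments(inj, 15, values=naive).loc["Site 1", "var"]
        assert abs(var_robust - var_clean) / var_clean < 0.05
        assert var_naive < 0.7 * var_clean  # naive fit shrinks it substantially

    def test_robust_mode_needs_two_rows_per_site(self, two_site_fixture):
        Y, sites = two_site_fixture
        mask = sites == "a"
        mask[:1] = False  # leaves exactly 1 unflagged row in site a
        with pytest.raises(ValidationError):
            harmonize(Y, sites, exclude_mask=mask)

    def test_fit_json_roundtrip(self, two_site_fixture, tmp_path):
        Y, sites = two_site_fixture
        _, fit = harmonize(Y, sites)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        loaded = CombatFit.from_json(path)
        np.testing.assert_allclose(loaded.gamma_star, fit.gamma_star)
        np.testing.assert_allclose(loaded.sigma_hat, fit.sigma_hat)
        assert loaded.sites == fit.sites


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_matches_bioconductor_sva_combat(tmp_path):
    """Full EB path agrees with the reference Bioconductor implementation."""
    import pandas as pd

    ds = make_default_dataset(n_per_site=50, n_features=12, target_idp=5, seed=7)
    pd.DataFrame(ds.values).to_csv(tmp_path / "Y.csv", index=False)
    pd.Series(ds.site_labels).to_csv(tmp_path / "site.csv", index=False)
    script = textwrap.dedent(
        """
        suppressMessages(library(sva))
        args <- commandArgs(trailingOnly = TRUE)
        Y <- as.matrix(read.csv(file.path(args[1], 'Y.csv')))
        site <- read.csv(file.path(args[1], 'site.csv'))[[1]]
        out <- ComBat(dat = t(Y), batch = site, par.prior = TRUE)
        write.csv(t(out), file.path(args[1], 'sva.csv'), row.names = FALSE)
        """
    )
    (tmp_path / "oracle.R").write_text(script)
    proc = subprocess.run(
        ["Rscript", str(tmp_path / "oracle.R"), str(tmp_path)],
        capture_output=True, text=True, timeout=300,
    )
    assert proc.returncode == 0, proc.stderr
    reference = pd.read_csv(tmp_path / "sva.csv").to_numpy()
    mine, _ = harmonize(ds.values, ds.site_labels, eb=True)
    np.testing.assert_allclose(mine, reference, atol=1e-8)
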