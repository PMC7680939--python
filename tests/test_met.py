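"""MET mixed model: oracle agreement, FA recovery, BLUP behaviour."""

import numpy as np
import pandas as pd
import pytest

from metgain.errors import ConfigurationError, ValidationError
from metgain.met import (
    MetParams,
    MetSpec,
    _fast_loglik,
    _MetData,
    fit_met,
    predict_yield,
    reml_loglik,
)
from metgain.simulate import SimConfig, simulate_series
from oracles import dense_restricted_loglik, met_dense_V, met_site_design


def _random_params(data, rng, variant="fa", k=1):
    s = data.s
    lam = rng.normal(0.0, 0.4, (s, k)) if variant == "fa" else np.zeros((s, 0))
    psi = rng.uniform(0.02, 0.1, s) if variant != "no_gxe" else np.zeros(s)
    return MetParams(
        data.sites, variant, float(rng.uniform(0.05, 0.3)),
        rng.uniform(0.01, 0.08, s), lam, psi, float(rng.uniform(0.1, 0.3)),
    )


def _small_records(seed, n_geno=4, sites={"ME1": 2, "ME4": 1}):
    cfg = SimConfig(n_trials=1, n_genotypes=n_geno, n_sites_per_me=sites,
                    n_reps=2, n_subblocks=2, seed=seed)
    records, _, truth = simulate_series(cfg)
    return records, truth


@pytest.mark.parametrize("variant", ["fa", "diagonal", "no_gxe"])
def test_reml_matches_dense_oracle(variant):
    """Woodbury evaluation equals the error-contrast density of the fully
    assembled marginal covariance, for 20 random small instances."""
    rng = np.random.default_rng(0)
    for i in range(20):
        records, _ = _small_records(seed=100 + i)
        data = _MetData(records)
        params = _random_params(data, rng, variant=variant)
        sigma = None if variant == "no_gxe" else params.sigma_ge
        V = met_dense_V(records, params.sigma2_g, params.rep_variances, sigma,
                        params.sigma2_e)
        X = met_site_design(records)
        oracle = dense_restricted_loglik(records["yield"], X, V)
        assert reml_loglik(records, params) == pytest.approx(oracle, abs=1e-8)


def test_fast_path_equals_general_path():
    """The balanced factorised likelihood equals the Woodbury evaluation."""
    rng = np.random.default_rng(3)
    records, _ = _small_records(seed=7, n_geno=10, sites={"ME1": 2, "ME4": 2})
    data = _MetData(records)
    assert data.balanced_stats is not None
    for _ in range(5):
        params = _random_params(data, rng)
        fast = _fast_loglik(data, params.sigma2_g, params.sigma_ge,
                            params.sigma2_e, rep_variances=params.rep_variances)
        assert fast == pytest.approx(data.general_loglik(params), abs=1e-8)


def test_degenerate_limit_is_ols_residual_likelihood():
    """All random variances at ~0: the restricted likelihood reduces to the
    residual likelihood of the fixed site-means model."""
    records, _ = _small_records(seed=9)
    data = _MetData(records)
    s2e = 0.21
    params = MetParams(data.sites, "no_gxe", 1e-12, np.full(data.s, 1e-12),
                       np.zeros((data.s, 0)), np.zeros(data.s), s2e)
    y = records["yield"].to_numpy()
    X = met_site_design(records)
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    n, p = X.shape
    expected = -0.5 * ((n - p) * (np.log(2 * np.pi) + np.log(s2e))
                       + resid @ resid / s2e)
    assert reml_loglik(records, params) == pytest.approx(expected, abs=1e-6)


def test_duplicated_records_change_the_likelihood():
    """Doubling every plot and halving sigma2_e must not leave the value
    unchanged; both evaluations still match the dense oracle."""
    rng = np.random.default_rng(5)
    records, _ = _small_records(seed=11)
    dup = pd.concat([records, records.assign(rep=records["rep"] + 2)],
                    ignore_index=True)
    data1, data2 = _MetData(records), _MetData(dup)
    p1 = _random_params(data1, rng)
    p2 = MetParams(p1.sites, p1.variant, p1.sigma2_g, p1.rep_variances,
                   p1.loadings, p1.specific_vars, p1.sigma2_e / 2)
    l1, l2 = reml_loglik(records, p1), reml_loglik(dup, p2)
    assert abs(l1 - l2) > 1e-3
    V2 = met_dense_V(dup, p2.sigma2_g, p2.rep_variances, p2.sigma_ge, p2.sigma2_e)
    oracle2 = dense_restricted_loglik(dup["yield"], met_site_design(dup), V2)
    assert l2 == pytest.approx(oracle2, abs=1e-8)


def test_nested_variant_likelihood_ordering(small_series):
    records, _, _ = small_series
    lls = {
        v: fit_met(records, MetSpec(model_variant=v, seed=2)).reml_loglik
        for v in ("fa", "diagonal", "cs", "no_gxe")
    }
    assert lls["fa"] >= lls["diagonal"] - 1e-6
    assert lls["diagonal"] >= lls["cs"] - 1e-6
    assert lls["cs"] >= lls["no_gxe"] - 1e-6


def test_blup_means_are_centred(small_fit):
    assert abs(small_fit.blup_g.mean()) < 1e-8
    assert small_fit.blup_ge.mean(axis=0).abs().max() < 1e-6


def test_sigma_ge_is_psd_with_valid_correlations(small_fit):
    w = np.linalg.eigvalsh(small_fit.Sigma_ge.to_numpy())
    assert w.min() > -1e-10
    corr = small_fit.ge_correlations().to_numpy()
    assert np.nanmax(np.abs(corr)) <= 1.0 + 1e-10


def test_no_signal_data_shrinks_blups():
    """sigma_g = 0 and no interaction: genotype BLUPs shrink to ~0."""
    means = []
    for seed in range(5):
        cfg = SimConfig(n_trials=1, n_genotypes=50, n_subblocks=5,
                        n_sites_per_me={"ME1": 6}, sigma_g=0.0, sigma_sb=0.0,
                        loading_scale=0.0, psi_range=(0.0, 0.0), fa_order=0,
                        trend_pct_per_year=0.0, seed=seed)
        records, _, _ = simulate_series(cfg)
        fit = fit_met(records, MetSpec(model_variant="no_gxe", seed=seed))
        means.append(fit.blup_g.abs().mean())
    assert np.mean(means) < 0.02


def test_rank_one_truth_recovers_extreme_correlations():
    """Psi ~ 0 and one factor: fitted between-site GE correlations near +-1."""
    cfg = SimConfig(n_trials=1, n_genotypes=100, n_subblocks=2, n_reps=2,
                    n_sites_per_me={"ME1": 3, "ME4": 1}, sigma_e=0.15,
                    loading_scale=0.8, psi_range=(1e-4, 2e-4), fa_order=1,
                    seed=17)
    records, _, truth = simulate_series(cfg)
    fit = fit_met(records, MetSpec(model_variant="fa", fa_order=1, seed=17))
    corr = fit.ge_correlations().to_numpy()
    off = corr[~np.eye(len(corr), dtype=bool)]
    assert np.all(np.abs(np.abs(off) - 1.0) < 0.1)


def test_recovery_improves_with_more_genotypes():
    errs = {}
    for n_geno in (40, 200):
        errs[n_geno] = []
        for seed in range(5):
            cfg = SimConfig(n_trials=1, n_genotypes=n_geno, n_subblocks=4,
                            n_sites_per_me={"ME1": 2, "ME4": 1}, fa_order=1,
                            seed=seed)
            records, _, truth = simulate_series(cfg)
            fit = fit_met(records, MetSpec(model_variant="fa", fa_order=1, seed=seed))
            T = truth.true_Sigma_ge[1].to_numpy()
            errs[n_geno].append(
                np.linalg.norm(fit.Sigma_ge.to_numpy() - T) / np.linalg.norm(T)
            )
    assert np.median(errs[200]) <= np.median(errs[40])


def test_noise_free_predictions_reproduce_truth():
    """Essentially noise-free complete data: site + genotype truth is
    reproduced.  The local check is excluded: its true effect is
    site-specific by design, which no exchangeable-genotype model can (or
    should) reproduce exactly."""
    cfg = SimConfig(n_trials=1, n_genotypes=10, n_subblocks=2,
                    n_sites_per_me={"ME1": 2, "ME4": 1}, sigma_g=0.3,
                    sigma_sb=0.0, sigma_e=1e-4, sigma_rep=0.0,
                    loading_scale=0.0, psi_range=(0.0, 0.0), fa_order=0,
                    seed=23)
    records, _, truth = simulate_series(cfg)
    records = records[records["genotype"] != "LOCAL_CHECK"]
    fit = fit_met(records, MetSpec(model_variant="no_gxe", seed=1))
    eff = truth.true_genotype_effects[1]
    for g in fit.genotypes:
        for site in fit.sites:
            true_val = truth.site_means[site] + eff[g]
            assert predict_yield(fit, g, site) == pytest.approx(true_val, abs=1e-3)


def test_predict_yield_identities(small_fit):
    fit = small_fit
    g = fit.genotypes[5]
    per_site = [predict_yield(fit, g, s) for s in fit.sites]
    assert predict_yield(fit, g, "overall") == pytest.approx(np.mean(per_site), abs=1e-10)
    me1 = [s for s in fit.sites if s.startswith("ME1")]
    assert predict_yield(fit, g, me1) == pytest.approx(
        np.mean([predict_yield(fit, g, s) for s in me1]), abs=1e-10
    )
    with pytest.raises(KeyError):
        predict_yield(fit, "NOPE", "overall")
    with pytest.raises(KeyError):
        predict_yield(fit, g, "NOSITE")


def test_no_gxe_site_prediction_is_additive(small_series):
    records, _, _ = small_series
    fit = fit_met(records, MetSpec(model_variant="no_gxe", seed=3))
    g = fit.genotypes[0]
    s = fit.sites[0]
    assert predict_yield(fit, g, s) == pytest.approx(
        fit.site_means[s] + fit.blup_g[g], abs=1e-12
    )


def test_blups_vanish_as_residual_variance_grows(small_series):
    records, _, _ = small_series
    fit = fit_met(records, MetSpec(model_variant="fa", fa_order=1, seed=2))
    data = _MetData(records)
    params = MetParams(
        fit.sites, "fa", fit.sigma2_g, fit.rep_variances.to_numpy(),
        fit.loadings.to_numpy(), fit.specific_vars.to_numpy(), 1e6,
    )
    _, blup_g, blup_ge, _ = data.general_solve(params)
    assert blup_g.abs().max() < 1e-2
    assert blup_ge.abs().to_numpy().max() < 1e-2


def test_configuration_and_validation_errors(small_series):
    records, _, _ = small_series
    with pytest.raises(ConfigurationError):
        fit_met(records, MetSpec(model_variant="fa", fa_order=6))
    with pytest.raises(ConfigurationError):
        fit_met(records, MetSpec(model_variant="banana"))
    one_site = records[records["site"] == records["site"].iloc[0]]
    with pytest.raises(ValidationError):
        fit_met(one_site)


def test_unbalanced_data_supported():
    cfg = SimConfig(n_trials=1, n_genotypes=10, n_subblocks=2,
                    n_sites_per_me={"ME1": 2, "ME4": 1},
                    missing_site_rate=0.15, seed=31)
    records, _, _ = simulate_series(cfg)
    data = _MetData(records)
    assert data.balanced_stats is None
    fit = fit_met(records, MetSpec(model_variant="diagonal", seed=1, n_starts=1))
    assert np.isfinite(fit.reml_loglik)
    assert abs(fit.blup_g.mean()) < 1e-8
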