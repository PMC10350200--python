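"""Weighted phylogenetic regression: GLS core, λ profiling, and the suite."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import multivariate_normal

from oncophylo.pgls import (
    RegressionDesign,
    default_analysis_suite,
    fit_pgls,
    gls_profile_loglik,
    mvn_gls_loglik,
    run_regression_suite,
)
from oncophylo.phylo import PhyloCovariance, read_newick, vcv
from oncophylo.simulate import SimulationConfig, simulate_species_data, simulate_tree


def _star_design(rng, n=40):
    taxa = tuple(f"S{i}" for i in range(n))
    x = rng.normal(size=n)
    y = 1.0 + 2.0 * x + rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    design = RegressionDesign(taxa, y, X, ("intercept", "x"), np.full(n, 50.0))
    cov = PhyloCovariance(taxa, np.eye(n))
    return design, cov, X, y


def test_star_tree_equal_weights_reduces_to_ols(rng):
    """With no phylogenetic structure and equal weights, PGLS is exactly OLS."""
    design, cov, X, y = _star_design(rng)
    fit = fit_pgls(design, cov)
    ols = sm.OLS(y, X).fit()
    assert np.allclose(fit.beta, ols.params, atol=1e-8)
    assert np.allclose(fit.se, ols.bse, atol=1e-8)
    assert np.allclose(fit.tvalues, ols.tvalues, atol=1e-8)
    assert np.allclose(fit.pvalues, ols.pvalues, atol=1e-8)
    assert np.allclose(fit.r2, ols.rsquared, atol=1e-8)


def test_fixed_variance_loglik_matches_brute_force_density():
    """3-taxon GLS log-likelihood equals the direct MVN density at β̂."""
    tree = read_newick("((A:1,B:1):1,C:2);")
    cov = vcv(tree)
    y = np.array([3.0, 2.5, 4.0])
    X = np.ones((3, 1))
    V = 1.7 * cov.matrix + np.diag([0.3, 0.2, 0.5])
    ll = mvn_gls_loglik(y, X, V)
    L = np.linalg.cholesky(V)
    Xw, yw = np.linalg.solve(L, X), np.linalg.solve(L, y)
    beta = np.linalg.lstsq(Xw, yw, rcond=None)[0]
    brute = multivariate_normal(mean=(X @ beta), cov=V).logpdf(y)
    assert ll == pytest.approx(brute, abs=1e-10)


def _synthetic_design(seed, n_species=50, **cfg_kw):
    cfg = SimulationConfig(
        seed=seed,
        n_species=n_species,
        mean_prevalence=30.0,
        clade_offsets=(0.0, 0.0, 0.0),
        **cfg_kw,
    )
    tree = simulate_tree(cfg)
    life, prev, _ = simulate_species_data(cfg, tree)
    x = np.log10(life["adult_weight_g"].to_numpy())
    design = RegressionDesign(
        tuple(prev["scientific_name"]),
        prev["p_neo"].to_numpy(),
        np.column_stack([np.ones(n_species), x]),
        ("intercept", "log10_weight"),
        prev["n"].to_numpy(),
    )
    return design, vcv(tree)


def test_profile_loglik_continuous_in_lambda():
    design, cov = _synthetic_design(5)
    grid = np.linspace(0, 1, 101)
    lls = np.array([gls_profile_loglik(design, cov, lam) for lam in grid])
    jumps = np.abs(np.diff(lls))
    assert np.all(np.isfinite(lls))
    assert jumps.max() < 0.05 * (np.ptp(lls) + 1.0)


@pytest.mark.parametrize("seed", [11, 12, 13])
def test_lambda_hat_matches_grid_search(seed):
    design, cov = _synthetic_design(seed, lambda_true=float(seed % 3) / 2)
    fit = fit_pgls(design, cov)
    grid = np.linspace(0, 1, 201)
    lls = [gls_profile_loglik(design, cov, lam) for lam in grid]
    assert abs(fit.lambda_hat - grid[int(np.argmax(lls))]) <= 1.0 / 200 + 1e-12


def test_scale_equivariance():
    design, cov = _synthetic_design(21)
    fit1 = fit_pgls(design, cov)
    scaled = RegressionDesign(
        design.species, 10.0 * design.y, design.X, design.coef_names, design.n_counts
    )
    fit2 = fit_pgls(scaled, cov)
    assert np.allclose(fit2.beta, 10.0 * fit1.beta, rtol=1e-5)
    assert fit2.lambda_hat == pytest.approx(fit1.lambda_hat, abs=1e-3)
    assert np.allclose(fit2.tvalues, fit1.tvalues, rtol=1e-5)
    assert np.allclose(fit2.pvalues, fit1.pvalues, rtol=1e-4, atol=1e-12)


def test_fixed_lambda_self_consistency():
    design, cov = _synthetic_design(31)
    fit = fit_pgls(design, cov)
    conditioned = fit_pgls(design, cov, lambda_fixed=fit.lambda_hat)
    assert np.allclose(conditioned.beta, fit.beta, rtol=1e-8)
    assert conditioned.loglik == pytest.approx(fit.loglik, abs=1e-8)


def test_doubling_necropsies_shrinks_outlier_residual(rng):
    """More necropsies halve the sampling variance and pull the fit inward."""
    n = 12
    taxa = tuple(f"S{i}" for i in range(n))
    x = np.linspace(0, 1, n)
    y = 2.0 + 3.0 * x
    y[-1] += 15.0  # one poorly-sampled outlier species
    X = np.column_stack([np.ones(n), x])
    counts = np.full(n, 100.0)
    counts[-1] = 10.0
    cov = PhyloCovariance(taxa, np.eye(n))

    def outlier_resid(c):
        fit = fit_pgls(
            RegressionDesign(taxa, y, X, ("i", "x"), c), cov, lambda_fixed=0.0
        )
        return abs(y[-1] - X[-1] @ fit.beta)

    doubled = counts.copy()
    doubled[-1] *= 2
    assert outlier_resid(doubled) <= outlier_resid(counts) + 1e-9


def test_rank_deficient_design_raises():
    n = 10
    taxa = tuple(f"S{i}" for i in range(n))
    X = np.column_stack([np.ones(n), np.full(n, 3.0)])  # constant predictor
    design = RegressionDesign(
        taxa, np.arange(n, dtype=float), X, ("i", "x"), np.full(n, 30.0)
    )
    with pytest.raises(np.linalg.LinAlgError, match="rank-deficient"):
        fit_pgls(design, PhyloCovariance(taxa, np.eye(n)))


def test_too_few_species_raises():
    taxa = ("A", "B", "C")
    design = RegressionDesign(
        taxa,
        np.array([1.0, 2.0, 3.0]),
        np.column_stack([np.ones(3), [0.0, 1.0, 2.0]]),
        ("i", "x"),
        np.full(3, 30.0),
    )
    with pytest.raises(ValueError, match="species"):
        fit_pgls(design, PhyloCovariance(taxa, np.eye(3)))


# ---------------------------------------------------------------------------
# the analysis suite


def test_default_suite_has_28_analyses():
    suite = default_analysis_suite()
    assert len(suite) == 28
    assert sum(1 for s in suite if s.subset == "Mammalia") == 4
    assert sum(1 for s in suite if len(s.predictors) > 1) == 3


def test_regression_suite_shapes_and_fdr(small_study):
    out = run_regression_suite(
        small_study["prevalence"],
        small_study["life_history"],
        small_study["tree"],
    )
    # metabolic rate exists only for mammals; every analysis still runs
    assert out["analysis"].nunique() == 28
    multi = out[out["analysis"] == "p_neo~adult_weight_g+gestation_months"]
    assert list(multi["coef"]) == ["intercept", "log10_adult_weight_g", "log10_gestation_months"]
    slopes = out[out["coef"] != "intercept"]
    assert slopes["p_adj"].notna().all()
    assert (slopes["p_adj"] >= slopes["p"] - 1e-12).all()
    assert out.loc[out["coef"] == "intercept", "p_adj"].isna().all()


def test_suite_skips_missing_predictor_column(small_study, caplog):
    life = small_study["life_history"].drop(columns=["litter_size"])
    out = run_regression_suite(
        small_study["prevalence"], life, small_study["tree"]
    )
    assert out["analysis"].nunique() == 28 - 5  # 3 univariate + 2 mammal-only
    assert not any("litter_size" in a for a in out["analysis"])
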