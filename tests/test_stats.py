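"""Nonparametric tests and FDR control against independent oracles."""

import numpy as np
import pytest
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

from oncophylo.records import DiagnosisDictionary
from oncophylo.stats import (
    bh_fdr,
    kruskal_wallis,
    ks_two_sample,
    pearson,
    scaled_age_comparison,
)

from conftest import make_record


# --------------------------------------------------------------------- KW


def test_kruskal_wallis_hand_example():
    res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
    assert res.statistic == pytest.approx(3.857, abs=5e-4)


def test_kruskal_wallis_identical_groups():
    res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
    assert res.statistic == 0.0
    res2 = kruskal_wallis([[5, 5], [5, 5, 5]])
    assert res2.statistic == 0.0 and res2.p == 1.0


@pytest.mark.parametrize("seed", range(5))
def test_kruskal_wallis_matches_scipy(seed, rng):
    r = np.random.default_rng(seed)
    groups = [r.integers(0, 8, size=r.integers(3, 15)).astype(float) for _ in range(3)]
    res = kruskal_wallis(groups)
    ref = sps.kruskal(*groups)
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
    assert res.p == pytest.approx(ref.pvalue, abs=1e-10)


def test_kruskal_wallis_exact_vs_monte_carlo(rng):
    groups = [[1.0, 4.0, 2.5], [3.0, 0.5, 5.0]]
    exact = kruskal_wallis(groups, exact=True)
    observed = kruskal_wallis(groups).statistic
    pooled = np.concatenate(groups)
    hits = 0
    reps = 4000
    for _ in range(reps):
        perm = rng.permutation(pooled)
        h = kruskal_wallis([perm[:3], perm[3:]]).statistic
        hits += h >= observed - 1e-12
    assert exact.p == pytest.approx(hits / reps, abs=0.03)


def test_kruskal_wallis_input_validation():
    with pytest.raises(ValueError):
        kruskal_wallis([[1.0, 2.0]])
    with pytest.raises(ValueError):
        kruskal_wallis([[1.0], []])


# --------------------------------------------------------------------- KS


def test_ks_trivial_cases():
    assert ks_two_sample([1, 2, 3], [1, 2, 3]).statistic == 0.0
    assert ks_two_sample([1, 2, 3], [10, 11]).statistic == 1.0


def _brute_force_d(x, y):
    d = 0.0
    for t in np.concatenate([x, y]):
        fx = np.mean(np.asarray(x) <= t)
        fy = np.mean(np.asarray(y) <= t)
        d = max(d, abs(fx - fy))
    return d


@pytest.mark.parametrize("seed", range(5))
def test_ks_statistic_matches_brute_force_and_scipy(seed):
    r = np.random.default_rng(seed)
    x = r.normal(size=r.integers(4, 15))
    y = r.normal(0.5, 1.2, size=r.integers(4, 15))
    res = ks_two_sample(x, y)
    assert res.statistic == pytest.approx(_brute_force_d(x, y), abs=1e-10)
    ref = sps.ks_2samp(x, y, method="asymp")
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)


def test_ks_exact_permutation_on_tiny_sample():
    x, y = [0.1, 0.9, 0.4], [0.5, 0.7, 1.4, 2.0]
    res = ks_two_sample(x, y, exact=True)
    ref = sps.ks_2samp(x, y, method="exact")
    # permutation tail at the observed D equals the exact distribution tail
    assert res.p == pytest.approx(ref.pvalue, abs=1e-10)


# ---------------------------------------------------------------- Pearson


def test_pearson_perfect_correlations():
    x = np.arange(5.0)
    assert pearson(x, x).statistic == pytest.approx(1.0)
    assert pearson(x, -x).statistic == pytest.approx(-1.0)


def test_pearson_matches_scipy_on_toy_points():
    x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
    y = np.array([2.2, 1.9, 3.1, 2.4, 4.4])
    res = pearson(x, y)
    ref = sps.pearsonr(x, y)
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
    assert res.p == pytest.approx(ref.pvalue, abs=1e-10)
    # covariance-formula oracle
    r_manual = np.cov(x, y, bias=True)[0, 1] / (np.std(x) * np.std(y))
    assert res.statistic == pytest.approx(r_manual, abs=1e-10)


def test_pearson_zero_variance_errors():
    with pytest.raises(ValueError):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# --------------------------------------------------------------------- BH


def test_bh_hand_examples():
    assert bh_fdr([0.03]).adjusted[0] == pytest.approx(0.03)
    res = bh_fdr([0.005, 0.01, 0.03, 0.04])
    assert np.allclose(res.adjusted, [0.02, 0.02, 0.04, 0.04])
    assert not bh_fdr([1.0, 1.0, 1.0]).reject.any()


@pytest.mark.parametrize("seed", range(5))
def test_bh_matches_statsmodels(seed):
    r = np.random.default_rng(seed)
    p = r.uniform(size=12)
    res = bh_fdr(p, q=0.10)
    reject_ref, p_ref, *_ = multipletests(p, alpha=0.10, method="fdr_bh")
    assert np.allclose(res.adjusted, p_ref, atol=1e-12)
    assert np.array_equal(res.reject, reject_ref)
    assert np.all(res.adjusted >= res.raw - 1e-15)


def test_bh_rejects_invalid_pvalues():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_fdr([])


def test_bh_controls_fdr_in_mixture_simulation():
    """Empirical FDR stays near or below q in a null/alternative mixture."""
    rng_ = np.random.default_rng(0)
    q = 0.10
    fdps = []
    for _ in range(400):
        null_p = rng_.uniform(size=15)
        alt_p = rng_.beta(0.1, 8.0, size=5)  # concentrated near zero
        p = np.concatenate([null_p, alt_p])
        rej = bh_fdr(p, q=q).reject
        n_rej = rej.sum()
        fdps.append(rej[:15].sum() / n_rej if n_rej else 0.0)
    assert np.mean(fdps) <= q + 0.03


# ------------------------------------------------------- scaled ages


def _aged_records(n_per_arm, shift, lifespan=120.0, clade="Mammalia", start=0):
    rng_ = np.random.default_rng(7)
    recs = []
    for i in range(n_per_arm):
        recs.append(
            make_record(
                start + i,
                terms=["lymphoma"],
                clade=clade,
                scientific_name="Mustela putorius",
                age_at_death_months=float(
                    lifespan * (0.2 + 0.5 * rng_.random() + shift)
                ),
            )
        )
        recs.append(
            make_record(
                start + 1000 + i,
                terms=[],
                clade=clade,
                scientific_name="Mustela putorius",
                age_at_death_months=float(lifespan * (0.2 + 0.5 * rng_.random())),
            )
        )
    return recs


@pytest.fixture(scope="module")
def lifespan_table():
    import pandas as pd

    return pd.DataFrame(
        {"scientific_name": ["Mustela putorius"], "max_longevity_months": [120.0]}
    )


def test_scaled_age_shift_detected(lifespan_table):
    d = DiagnosisDictionary({"lymphoma": "malignant"})
    results, density = scaled_age_comparison(
        _aged_records(200, shift=0.3), lifespan_table, d
    )
    res = results["Mammalia"]
    assert res.statistic > 0.2
    assert res.p < 1e-4
    assert set(density["arm"]) == {"neoplasia", "non_neoplasia"}


def test_scaled_age_skips_underfilled_clades(lifespan_table, caplog):
    d = DiagnosisDictionary({"lymphoma": "malignant"})
    records = _aged_records(1, shift=0.0)
    results, _ = scaled_age_comparison(records, lifespan_table, d)
    assert results == {}


# ------------------------------------------------------ property tests

from hypothesis import given, settings
from hypothesis import strategies as st


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
@settings(deadline=None, max_examples=60, derandomize=True)
def test_bh_adjustment_bounds_and_monotonicity(pvals):
    res = bh_fdr(np.array(pvals, dtype=float))
    assert np.all(res.adjusted >= res.raw - 1e-15)
    assert np.all(res.adjusted <= 1.0 + 1e-15)
    order = np.argsort(res.raw, kind="mergesort")
    assert np.all(np.diff(res.adjusted[order]) >= -1e-15)
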