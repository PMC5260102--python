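"""Dependence-corrected Fisher combination and q-values."""

import logging

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glints import combination as comb
from glints.exceptions import GlintsError, MissingResultError


# ---------------------------------------------------------------------------
# z transform
# ---------------------------------------------------------------------------

def test_z_transform_values():
    assert comb.z_transform(0.5) == pytest.approx(0.0, abs=1e-12)
    assert comb.z_transform(0.025) == pytest.approx(1.959964, abs=1e-5)
    assert np.isfinite(comb.z_transform(1.0))
    assert np.isfinite(comb.z_transform(0.0))
    # monotone decreasing
    grid = np.linspace(0.01, 0.99, 50)
    assert np.all(np.diff(comb.z_transform(grid)) < 0)


# ---------------------------------------------------------------------------
# Correlation estimation, shrinkage, covariance polynomial
# ---------------------------------------------------------------------------

def test_identical_columns_have_unit_correlation():
    p = np.random.default_rng(0).uniform(0.01, 0.99, size=100)
    rho, n_pairs = comb.estimate_source_correlations(np.column_stack([p, p]))
    assert rho[0, 1] == pytest.approx(1.0)
    assert n_pairs[0, 1] == 100


def test_independent_columns_have_small_correlation():
    rng = np.random.default_rng(1)
    p = rng.uniform(1e-6, 1, size=(10000, 2))
    rho, _ = comb.estimate_source_correlations(p)
    assert abs(rho[0, 1]) < 0.05


def test_sparse_pair_falls_back_to_zero(caplog):
    p = np.full((5, 2), np.nan)
    p[:, 0] = 0.5
    p[:2, 1] = [0.3, 0.4]  # only 2 complete rows for the pair
    with caplog.at_level(logging.WARNING, logger="glints.combination"):
        rho, n_pairs = comb.estimate_source_correlations(p)
    assert rho[0, 1] == 0.0
    assert n_pairs[0, 1] == 2
    assert any("treated as independent" in r.message for r in caplog.records)


def test_shrinkage_arithmetic_and_fixed_points():
    assert comb.shrink_correlation(0.0, 13) == 0.0
    assert comb.shrink_correlation(1.0, 13) == 1.0
    assert comb.shrink_correlation(-1.0, 13) == -1.0
    assert comb.shrink_correlation(0.5, 13) == pytest.approx(0.515)


def test_cov_polynomial_values():
    assert comb.cov_minus2logp(0.0, 100) == 0.0
    # sum of the three n-free coefficients approaches Var(chi2_2) = 4
    assert comb.cov_minus2logp(1.0, 1e12) == pytest.approx(3.999574, abs=1e-6)
    assert comb.cov_minus2logp(0.5, 100) == pytest.approx(1.811906, abs=1e-6)


# ---------------------------------------------------------------------------
# Moment-matched null
# ---------------------------------------------------------------------------

def test_brown_null_limits():
    for k in (1, 2, 5, 17):
        null = comb.brown_null(comb.independent_dependence_model(k))
        assert (null.eta, null.v) == (1.0, 2.0 * k)
    dep = comb.independent_dependence_model(5)
    dep.cov[:] = 4.0  # perfect dependence
    null = comb.brown_null(dep)
    assert (null.eta, null.v) == (5.0, 2.0)


def test_brown_null_matches_moments():
    """Fitted (eta, v) reproduce E[U] = 2K and Var[U] = sum(cov) exactly."""
    rng = np.random.default_rng(2)
    k = 6
    dep = comb.independent_dependence_model(k)
    rho = rng.uniform(-0.3, 0.9, size=(k, k))
    rho = (rho + rho.T) / 2
    cov = comb.cov_minus2logp(rho, 500)
    np.fill_diagonal(cov, 4.0)
    dep.cov = cov
    null = comb.brown_null(dep)
    assert null.eta * null.v == pytest.approx(2.0 * k, rel=1e-12)
    assert 2.0 * null.eta**2 * null.v == pytest.approx(cov.sum(), rel=1e-12)


def test_combine_examples():
    null = comb.brown_null(comb.independent_dependence_model(2))
    result = comb.combine_pvalues(comb.PValueVector(np.array([0.01, 0.01])), null)
    assert result.U == pytest.approx(18.42068, abs=1e-5)
    assert result.p_combined == pytest.approx(1.02103e-3, abs=1e-7)
    result = comb.combine_pvalues(comb.PValueVector(np.array([1.0, 1.0])), null)
    assert result.U == 0.0 and result.p_combined == 1.0


def test_missing_source_reduces_k():
    dep = comb.independent_dependence_model(3)
    pv = comb.PValueVector(np.array([0.02, np.nan, 0.3]))
    null = comb.brown_null(dep, pv.mask)
    assert null.v == 4.0  # K_effective = 2
    result = comb.combine_pvalues(pv, null)
    assert result.k_effective == 2
    expected_u = -2.0 * (np.log(0.02) + np.log(0.3))
    assert result.U == pytest.approx(expected_u)
    with pytest.raises(MissingResultError):
        comb.combine_pvalues(comb.PValueVector(np.array([np.nan, np.nan, np.nan])), null)


def test_combination_is_monotone_in_each_p():
    dep = comb.independent_dependence_model(4)
    null = comb.brown_null(dep)
    base = np.array([0.2, 0.4, 0.6, 0.8])
    p0 = comb.combine_pvalues(comb.PValueVector(base.copy()), null).p_combined
    for j in range(4):
        lowered = base.copy()
        lowered[j] = base[j] / 2
        assert comb.combine_pvalues(comb.PValueVector(lowered), null).p_combined < p0


def test_source_permutation_invariance():
    rng = np.random.default_rng(3)
    p = pd.DataFrame(rng.uniform(0.001, 1, size=(200, 5)),
                     columns=list("abcde"))
    p.iloc[rng.random((200, 5)) < 0.1] = np.nan
    p = p.mask(p.isna())
    out1 = comb.combine_matrix(p)
    perm = ["c", "a", "e", "b", "d"]
    out2 = comb.combine_matrix(p[perm])
    np.testing.assert_allclose(out1["U"], out2["U"], rtol=1e-12)
    np.testing.assert_allclose(out1["p_combined"], out2["p_combined"], rtol=1e-12)


def test_removing_an_equal_valued_source_preserves_order():
    rng = np.random.default_rng(4)
    p = pd.DataFrame(rng.uniform(0.001, 1, size=(50, 4)))
    p.loc[:, 3] = 0.37  # identical on the removed source
    full = comb.combine_matrix(p)["p_combined"]
    reduced = comb.combine_matrix(p.iloc[:, :3])["p_combined"]
    assert np.array_equal(np.argsort(full.to_numpy(), kind="stable"),
                          np.argsort(reduced.to_numpy(), kind="stable"))


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

def test_qvalues_bh_equivalence_with_pi0_fixed():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(5)
    p = rng.uniform(1e-6, 1, size=777)
    q = comb.compute_qvalues(p, pi0_mode="fixed")
    _, bh, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(q, bh, atol=1e-14)
    assert np.array_equal(
        comb.compute_qvalues(np.array([0.01, 0.02, 0.03]), pi0_mode="fixed"),
        np.array([0.03, 0.03, 0.03]),
    )


def test_qvalues_constant_and_order():
    q = comb.compute_qvalues(np.full(10, 0.2), pi0_mode="fixed")
    assert np.ptp(q) == 0.0
    rng = np.random.default_rng(6)
    p = rng.uniform(0.001, 1, size=500)
    q = comb.compute_qvalues(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-15)  # order-consistent with p
    pi0 = comb.estimate_pi0(p)
    assert np.all(q >= pi0 * p - 1e-15)         # q dominance
    assert np.all((0 < q) & (q <= 1))


def test_pi0_on_uniform_null_is_near_one():
    rng = np.random.default_rng(7)
    pi0 = comb.estimate_pi0(rng.uniform(0, 1, size=1000))
    assert 0.8 <= pi0 <= 1.0


def test_qvalue_input_validation():
    with pytest.raises(GlintsError):
        comb.compute_qvalues(np.array([]))
    with pytest.raises(GlintsError):
        comb.compute_qvalues(np.array([0.0, 0.5]))
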