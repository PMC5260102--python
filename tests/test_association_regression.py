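"""Multivariate phenotype~genotype regression and the association t test."""

import numpy as np
import pandas as pd
import pytest

from glints.association_regression import (
    DiseaseSpace,
    GeneSimilarityMeasure,
    RegressionInputs,
    association_test,
    build_regression_inputs,
    fit_mle,
    gene_association_pvalues,
    genotype_similarity,
)
from glints.exceptions import (
    DegenerateDesignError,
    DegenerateFitError,
    InsufficientDataError,
)


def make_measure(values, genes):
    return GeneSimilarityMeasure(
        name="m", phi=pd.DataFrame(values, index=genes, columns=genes)
    )


@pytest.fixture
def four_disease_space():
    diseases = ["D0", "D1", "D2", "D3"]
    rng = np.random.default_rng(0)
    mats = {}
    for name in ("UMLS", "MeSH", "HPO"):
        a = rng.uniform(0.1, 0.9, size=(4, 4))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        mats[name] = pd.DataFrame(a, index=diseases, columns=diseases)
    genes = {"D1": frozenset({"g1"}), "D2": frozenset({"g2", "g3"}), "D3": frozenset()}
    return DiseaseSpace(diseases=diseases, phenotype_sims=mats, disease_genes=genes)


# ---------------------------------------------------------------------------
# Genotype similarity
# ---------------------------------------------------------------------------

def test_genotype_similarity_sums_pairs():
    phi = make_measure([[1.0, 0.2, 0.3], [0.2, 1.0, 0.5], [0.3, 0.5, 1.0]],
                       ["g1", "g2", "h1"])
    assert genotype_similarity({"g1", "g2"}, {"h1"}, phi) == pytest.approx(0.8)
    assert genotype_similarity(set(), {"h1"}, phi) == 0.0
    # symmetry
    assert genotype_similarity({"h1"}, {"g1", "g2"}, phi) == pytest.approx(0.8)
    # unknown genes contribute zero
    assert genotype_similarity({"g1", "zz"}, {"h1"}, phi) == pytest.approx(0.3)


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def test_too_few_rows_is_insufficient_data(four_disease_space):
    phi = make_measure(np.eye(3), ["g0", "g1", "g2"])
    # D3 has no genes -> only 2 usable rows
    with pytest.raises(InsufficientDataError):
        build_regression_inputs("g0", "D0", four_disease_space, phi)


def test_query_disease_excluded_and_leave_out(four_disease_space):
    space = four_disease_space
    space.disease_genes = {
        "D0": frozenset({"gq"}),
        "D1": frozenset({"g1", "gq"}),
        "D2": frozenset({"g2"}),
        "D3": frozenset({"g3"}),
    }
    genes = ["gq", "g1", "g2", "g3", "gc"]
    phi = make_measure(np.full((5, 5), 0.5) + 0.5 * np.eye(5), genes)
    inputs = build_regression_inputs("gc", "D0", space, phi, leave_out=True)
    assert "D0" not in inputs.row_ids
    assert inputs.n == 3
    # gq removed from D1's set by leave-out: x(D1) counts only g1
    assert inputs.x[inputs.row_ids.index("D1")] == pytest.approx(0.5)
    no_lo = build_regression_inputs("gc", "D0", space, phi, leave_out=False)
    assert no_lo.x[no_lo.row_ids.index("D1")] == pytest.approx(1.0)


def test_leave_out_removes_candidate_self_matches(four_disease_space):
    space = four_disease_space
    space.disease_genes = {
        "D1": frozenset({"gc", "g1"}),
        "D2": frozenset({"g2"}),
        "D3": frozenset({"g3"}),
    }
    genes = ["gc", "g1", "g2", "g3"]
    phi = make_measure(np.full((4, 4), 0.25) + 0.75 * np.eye(4), genes)
    with_self = build_regression_inputs("gc", "D0", space, phi, leave_out=False)
    without = build_regression_inputs("gc", "D0", space, phi, leave_out=True)
    i = with_self.row_ids.index("D1")
    assert with_self.x[i] == pytest.approx(1.25)  # phi(gc,gc) + phi(gc,g1)
    assert without.x[without.row_ids.index("D1")] == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def test_exact_linear_fit():
    inputs = RegressionInputs(
        Y=np.array([[1.0], [3.0], [5.0]]), x=np.array([0.0, 1.0, 2.0]),
        row_ids=list("abc"), response_names=["y"],
    )
    fit = fit_mle(inputs)
    assert fit.beta_hat[0] == pytest.approx(2.0)
    assert fit.alpha_hat[0] == pytest.approx(1.0)
    assert fit.sigma_eps_hat[0, 0] == pytest.approx(0.0, abs=1e-14)


def test_identical_response_columns_give_equal_slopes():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(10)
    y = 0.5 + 0.8 * x + rng.standard_normal(10)
    inputs = RegressionInputs(
        Y=np.column_stack([y, y, y]), x=x, row_ids=[str(i) for i in range(10)],
        response_names=list("abc"),
    )
    fit = fit_mle(inputs)
    assert np.ptp(fit.beta_hat) == pytest.approx(0.0, abs=1e-14)


def test_constant_x_is_degenerate_design():
    inputs = RegressionInputs(
        Y=np.random.default_rng(0).standard_normal((5, 2)),
        x=np.ones(5), row_ids=list("abcde"), response_names=["y1", "y2"],
    )
    with pytest.raises(DegenerateDesignError):
        fit_mle(inputs)


def test_fit_matches_statsmodels_ols_per_column():
    import statsmodels.api as sm

    rng = np.random.default_rng(7)
    x = rng.standard_normal(20)
    Y = rng.standard_normal((20, 3)) + np.outer(x, [0.5, -1.0, 0.0])
    inputs = RegressionInputs(
        Y=Y, x=x, row_ids=[str(i) for i in range(20)], response_names=list("abc")
    )
    fit = fit_mle(inputs)
    X = sm.add_constant(x)
    for j in range(3):
        ols = sm.OLS(Y[:, j], X).fit()
        assert fit.alpha_hat[j] == pytest.approx(ols.params[0], abs=1e-10)
        assert fit.beta_hat[j] == pytest.approx(ols.params[1], abs=1e-10)
        assert fit.sigma_eps_hat[j, j] == pytest.approx(ols.mse_resid, rel=1e-10)
        lam = np.zeros(3)
        lam[j] = 1.0
        result = association_test(fit, inputs, lam=lam)
        assert result.T == pytest.approx(ols.tvalues[1], abs=1e-10)


# ---------------------------------------------------------------------------
# Association test
# ---------------------------------------------------------------------------

def test_negative_slope_gives_large_one_sided_p():
    rng = np.random.default_rng(2)
    x = np.linspace(0, 1, 15)
    Y = (1.0 - 2.0 * x + 0.05 * rng.standard_normal(15)).reshape(-1, 1)
    inputs = RegressionInputs(Y=Y, x=x, row_ids=[str(i) for i in range(15)],
                              response_names=["y"])
    result = association_test(fit_mle(inputs), inputs)
    assert result.T < 0
    assert result.p_analytical > 0.5


def test_exact_fit_is_degenerate():
    x = np.array([-1.0, 0.0, 1.0])
    inputs = RegressionInputs(Y=x.reshape(-1, 1), x=x, row_ids=list("abc"),
                              response_names=["y"])
    with pytest.raises(DegenerateFitError):
        association_test(fit_mle(inputs), inputs)


def test_missing_measures_propagate_as_nan(four_disease_space):
    space = four_disease_space
    space.disease_genes = {
        "D1": frozenset({"g1"}), "D2": frozenset({"g2"}), "D3": frozenset({"g3"}),
    }
    rng = np.random.default_rng(3)
    genes = ["gc", "g1", "g2", "g3"]
    a = rng.uniform(0, 1, (4, 4))
    good = make_measure((a + a.T) / 2, genes)
    # candidate gene absent -> x identically zero -> degenerate -> NaN
    missing = make_measure(np.eye(3), ["g1", "g2", "g3"])
    out = gene_association_pvalues(
        "gc", "D0", space, {"good": good, "missing": missing}
    )
    assert np.isfinite(out["good"])
    assert np.isnan(out["missing"])
    assert len(out) == 2


def test_planted_signal_ranks_causal_gene_first():
    """With a strong planted slope, the causal gene's association p-values
    are smaller than a random gene's."""
    from glints.synthetic_data import simulate_disease_space

    space, measures, truth = simulate_disease_space(
        n_diseases=30, n_genes=40, slope=0.5, noise_sd=0.05, seed=9,
        n_causal_genes=1, n_neutral_genes=10,
    )
    causal = truth["causal_genes"][0]
    query = truth["query_disease"]
    p_causal = gene_association_pvalues(causal, query, space, measures)
    p_neutral = gene_association_pvalues(
        truth["neutral_genes"][0], query, space, measures
    )
    assert p_causal.median() < p_neutral.median()
    assert p_causal.median() < 0.05
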