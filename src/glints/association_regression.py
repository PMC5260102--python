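"""Gene-disease association by multivariate phenotype~genotype regression.

Under the guilt-by-association principle, the phenotype similarity between
two diseases should be explained by the functional similarity of their
associated gene sets. For a candidate gene g and a query disease d, the
genotype similarity between d (assumed to be associated with g only) and
every other disease e is

    x_e = sum_{h in genes(e)} phi(g, h)

for a given gene functional-similarity measure phi. The p (= 3 by default:
UMLS, MeSH, HPO) phenotype similarities between d and the other diseases are
regressed on x simultaneously:

    Y = X Theta + E,   X = (1, x),   rows of E ~ N(0, Sigma_eps) iid.

Maximum likelihood gives the textbook closed forms

    beta_hat  = (x_c' x_c)^{-1} x_c' Y_c
    alpha_hat = y_bar - x_bar beta_hat
    Sigma_hat = (n-2)^{-1} E_hat' E_hat

and the association is tested one-sided via

    T = lambda' beta_hat / sqrt(lambda' (x_c' x_c)^{-1} Sigma_hat lambda)
      ~ t_{n-2}  under H0: lambda' beta = 0,

with p = P(t_{n-2} >= T). A positive combined slope indicates that diseases
phenotypically similar to d tend to carry genes functionally similar to g.
The design has a single regressor, so the "matrix inverse" is a scalar
division by x_c' x_c.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateDesignError,
    DegenerateFitError,
    InsufficientDataError,
    ValidationError,
)

logger = logging.getLogger(__name__)

_SYM_ATOL = 1e-8
_DIAG_ATOL = 1e-6


@dataclass
class DiseaseSpace:
    """Diseases, their phenotype-similarity matrices and known gene sets."""

    diseases: list[str]
    phenotype_sims: dict[str, pd.DataFrame]
    disease_genes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if not self.phenotype_sims:
            raise ValidationError("at least one phenotype-similarity matrix required")
        self.disease_genes = {
            d: frozenset(g) for d, g in self.disease_genes.items()
        }
        for name, mat in self.phenotype_sims.items():
            arr = mat.to_numpy(dtype=float)
            if not np.allclose(arr, arr.T, atol=_SYM_ATOL, equal_nan=True):
                raise ValidationError(f"phenotype matrix {name!r} is not symmetric")
            if not np.allclose(np.diag(arr), 1.0, atol=_DIAG_ATOL):
                raise ValidationError(
                    f"phenotype matrix {name!r} does not have a unit diagonal"
                )
            missing = set(self.diseases) - set(mat.index)
            if missing:
                raise ValidationError(
                    f"phenotype matrix {name!r} lacks diseases {sorted(missing)[:5]}"
                )

    @property
    def p(self) -> int:
        return len(self.phenotype_sims)

    @property
    def measure_names(self) -> list[str]:
        return list(self.phenotype_sims)

    @cached_property
    def _disease_index(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.diseases)}

    @cached_property
    def _sim_arrays(self) -> list[np.ndarray]:
        """Phenotype matrices as arrays aligned to ``self.diseases`` order."""
        return [
            self.phenotype_sims[m].loc[self.diseases, self.diseases].to_numpy(dtype=float)
            for m in self.measure_names
        ]


@dataclass
class GeneSimilarityMeasure:
    """One symmetric, non-negative gene x gene functional-similarity matrix."""

    name: str
    phi: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.phi.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T, atol=_SYM_ATOL, equal_nan=True):
            raise ValidationError(f"gene-similarity matrix {self.name!r} is not symmetric")
        if np.nanmin(arr) < -_SYM_ATOL:
            raise ValidationError(f"gene-similarity matrix {self.name!r} has negative entries")

    @property
    def genes(self) -> pd.Index:
        return self.phi.index

    @cached_property
    def _gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.phi.index)}

    @cached_property
    def _phi_values(self) -> np.ndarray:
        return self.phi.to_numpy(dtype=float)


@dataclass
class RegressionInputs:
    """Design for one (candidate gene, query disease, measure) regression."""

    Y: np.ndarray           # n x p phenotype similarities
    x: np.ndarray           # n genotype similarities
    row_ids: list[str]      # the n disease identifiers
    response_names: list[str]

    @property
    def n(self) -> int:
        return int(self.x.size)

    @property
    def p(self) -> int:
        return int(self.Y.shape[1])


@dataclass
class RegressionFit:
    """MLE point estimates for one regression."""

    alpha_hat: np.ndarray
    beta_hat: np.ndarray
    sigma_eps_hat: np.ndarray
    n: int
    p: int
    xtx_c: float            # centred x'x, reused by the test statistic
    x_bar: float


@dataclass
class AssociationResult:
    T: float
    p_analytical: float
    lam: np.ndarray


def genotype_similarity(
    D: Iterable[str], E: Iterable[str], phi: GeneSimilarityMeasure
) -> float:
    """Sum of pairwise gene functional similarities over D x E.

    Gene identifiers absent from the matrix contribute zero (logged at debug
    level), so the value is always defined.
    """
    index = phi._gene_index
    d_idx = [index[g] for g in D if g in index]
    e_idx = [index[g] for g in E if g in index]
    n_missing = sum(1 for g in D if g not in index) + sum(
        1 for g in E if g not in index
    )
    if n_missing:
        logger.debug(
            "%d gene(s) missing from measure %s contribute 0", n_missing, phi.name
        )
    if not d_idx or not e_idx:
        return 0.0
    return float(phi._phi_values[np.ix_(d_idx, e_idx)].sum())


def build_regression_inputs(
    gene: str,
    disease: str,
    space: DiseaseSpace,
    phi: GeneSimilarityMeasure,
    *,
    leave_out: bool = True,
    include_empty: bool = False,
) -> RegressionInputs:
    """One regression row per other disease with a non-empty gene set.

    With ``leave_out`` set, the candidate gene and every gene known to be
    associated with the query disease are removed from the other diseases'
    gene sets before computing x, mimicking evaluation with the query
    disease's genetics treated as unknown. ``include_empty`` keeps diseases
    whose gene set empties out, as x = 0 rows.
    """
    if disease not in space.diseases:
        raise ValidationError(f"query disease {disease!r} not in the disease space")
    removed: frozenset[str] = frozenset()
    if leave_out:
        removed = space.disease_genes.get(disease, frozenset()) | {gene}
    rows, xs, ids = [], [], []
    measure_names = space.measure_names
    sims = space._sim_arrays
    d_i = space._disease_index[disease]
    for e in space.diseases:
        if e == disease:
            continue
        genes_e = space.disease_genes.get(e, frozenset()) - removed
        if not genes_e and not include_empty:
            continue
        xs.append(genotype_similarity({gene}, genes_e, phi))
        e_i = space._disease_index[e]
        rows.append([float(m[d_i, e_i]) for m in sims])
        ids.append(e)
    if len(ids) < 3:
        raise InsufficientDataError(
            f"only {len(ids)} usable regression rows for gene {gene!r} vs "
            f"disease {disease!r} (need >= 3)"
        )
    return RegressionInputs(
        Y=np.asarray(rows, dtype=float),
        x=np.asarray(xs, dtype=float),
        row_ids=ids,
        response_names=measure_names,
    )


def fit_mle(inputs: RegressionInputs) -> RegressionFit:
    """Closed-form maximum-likelihood fit of the shared-design regression."""
    x, Y = inputs.x, inputs.Y
    n, p = inputs.n, inputs.p
    if n < 3:
        raise InsufficientDataError(f"n = {n} < 3 leaves no residual degrees of freedom")
    x_bar = float(x.mean())
    xc = x - x_bar
    xtx = float(xc @ xc)
    if xtx <= 0.0:
        raise DegenerateDesignError("genotype similarity x is constant across rows")
    y_bar = Y.mean(axis=0)
    Yc = Y - y_bar
    beta = (xc @ Yc) / xtx
    alpha = y_bar - x_bar * beta
    resid = Yc - np.outer(xc, beta)
    sigma = resid.T @ resid / (n - 2)
    sigma = (sigma + sigma.T) / 2.0  # enforce exact symmetry
    return RegressionFit(
        alpha_hat=alpha, beta_hat=beta, sigma_eps_hat=sigma,
        n=n, p=p, xtx_c=xtx, x_bar=x_bar,
    )


def association_test(
    fit: RegressionFit,
    inputs: RegressionInputs,
    lam: Sequence[float] | None = None,
) -> AssociationResult:
    """One-sided t test of H0: lambda' beta = 0 vs H1: lambda' beta > 0."""
    lam = np.ones(fit.p) if lam is None else np.asarray(lam, dtype=float)
    if lam.shape != (fit.p,):
        raise ValidationError(f"lambda must have length p = {fit.p}")
    s2 = float(lam @ fit.sigma_eps_hat @ lam)
    if not np.isfinite(s2) or s2 <= 0.0:
        raise DegenerateFitError(
            "zero residual variance in the lambda direction; association "
            "statistic undefined"
        )
    T = float(lam @ fit.beta_hat) / np.sqrt(s2 / fit.xtx_c)
    p = float(stats.t.sf(T, df=fit.n - 2))
    p = min(max(p, np.nextafter(0.0, 1.0)), np.nextafter(1.0, 0.0))
    return AssociationResult(T=float(T), p_analytical=p, lam=lam)


def gene_association_pvalues(
    gene: str,
    disease: str,
    space: DiseaseSpace,
    measures: Mapping[str, GeneSimilarityMeasure],
    *,
    lam: Sequence[float] | None = None,
    leave_out: bool = True,
) -> pd.Series:
    """Analytical association p per similarity measure; failures become NaN.

    Degenerate designs (gene absent from a measure, constant x, exact fits,
    too few rows) are downgraded to missing entries so the variant pipeline
    stays total; the failure is logged.
    """
    out = {}
    for name, measure in measures.items():
        try:
            inputs = build_regression_inputs(
                gene, disease, space, measure, leave_out=leave_out
            )
            fit = fit_mle(inputs)
            out[name] = association_test(fit, inputs, lam=lam).p_analytical
        except (InsufficientDataError, DegenerateDesignError, DegenerateFitError) as exc:
            logger.debug("measure %s for gene %s: %s", name, gene, exc)
            out[name] = np.nan
    return pd.Series(out, dtype=float)
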