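"""Dependence-corrected Fisher combination of p-values and pFDR q-values.

For K p-value sources, Fisher's statistic is U = sum_i V_i with
V_i = -2 log p_i. Under independence U ~ chi2_{2K}; the sources here
(functional scores, gene association measures) are correlated, so the null
of U is approximated by a scaled chi-squared eta * chi2_v matched on its
first two moments (Brown's method):

    E[U]   = 2K            =>  eta * v = 2K
    Var[U] = sum_ij cov(V_i, V_j)  =>  eta = Var[U] / (4K),  v = 2K / eta.

The covariance of each (V_i, V_j) pair is obtained from the Pearson
correlation of the normal-transformed p-values, z = Phi^{-1}(1 - p), via a
finite-sample shrinkage and the Kost-McDermott quartic polynomial

    cov(V_i, V_j) = a1 r + a2 r^2 + a3 r^3 + a4 r^4,
    a1 = 3.263119, a2 = 0.709866, a3 = 0.026589, a4 = -0.709866/n.

Diagonal entries are fixed at exactly Var(chi2_2) = 4, which makes the
reduction to classical Fisher exact when all correlations vanish. Missing
sources simply reduce K; the scaled-chi2 null is re-fitted per missingness
pattern. Combined p-values are converted to q-values controlling the
positive false discovery rate (Storey's procedure).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .exceptions import GlintsError, MissingResultError

logger = logging.getLogger(__name__)

#: Kost-McDermott polynomial coefficients for cov(-2 log p_i, -2 log p_j).
KOST_A1 = 3.263119
KOST_A2 = 0.709866
KOST_A3 = 0.026589
KOST_A4_NUM = -0.709866  # divided by the sample size n

_P_EPS = 1e-15
_P_FLOOR = 1e-300
DEFAULT_ETA_FLOOR = 1e-6


def z_transform(p):
    """Normal transformation z = Phi^{-1}(1 - p); p outside (0,1) is clamped.

    Monotone decreasing in p, with z(0.5) = 0. Values at or beyond the open
    interval bounds are clamped to [1e-15, 1 - 1e-15] (logged), keeping the
    output finite.
    """
    arr = np.asarray(p, dtype=float)
    clamped = np.clip(arr, _P_EPS, 1.0 - _P_EPS)
    n_invalid = int(np.sum(((arr <= 0.0) | (arr > 1.0)) & np.isfinite(arr)))
    if n_invalid:
        logger.warning("clamped %d p-value(s) outside (0,1] before z-transform", n_invalid)
    z = -ndtri(clamped)
    z = np.where(np.isfinite(arr), z, np.nan)
    return float(z) if z.ndim == 0 else z


def estimate_source_correlations(
    p_matrix, *, min_complete: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson correlations of z-transformed p-values.

    ``p_matrix`` is candidates x K (DataFrame or array, NaN = missing).
    Pairs with fewer than ``min_complete`` complete rows -- or undefined
    correlations (constant columns) -- are treated as independent (rho = 0,
    with a warning). Returns (rho_hat, n_pairs).
    """
    df = pd.DataFrame(p_matrix).astype(float)
    z = df.apply(lambda col: z_transform(col.to_numpy()))
    mask = df.notna().to_numpy()
    n_pairs = mask.T.astype(np.int64) @ mask.astype(np.int64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rho = z.corr(method="pearson", min_periods=min_complete).to_numpy()
    undefined = ~np.isfinite(rho)
    np.fill_diagonal(undefined, False)
    if undefined.any():
        logger.warning(
            "%d source pair(s) with < %d complete rows or zero variance "
            "treated as independent",
            int(undefined.sum()) // 2, min_complete,
        )
        rho[undefined] = 0.0
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    return rho, n_pairs


def shrink_correlation(rho_hat, n):
    """Finite-sample shrinkage rho~ = rho^ (1 + (1 - rho^2) / (2n - 1)).

    Fixed points at rho^ in {-1, 0, 1}; output clipped to [-1, 1].
    """
    rho = np.asarray(rho_hat, dtype=float)
    n = np.maximum(np.asarray(n, dtype=float), 2.0)
    out = rho * (1.0 + (1.0 - rho**2) / (2.0 * n - 1.0))
    out = np.clip(out, -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


def cov_minus2logp(rho_tilde, n):
    """Kost-McDermott covariance of (-2 log p_i, -2 log p_j) at correlation rho~."""
    r = np.asarray(rho_tilde, dtype=float)
    n = np.maximum(np.asarray(n, dtype=float), 1.0)
    out = KOST_A1 * r + KOST_A2 * r**2 + KOST_A3 * r**3 + (KOST_A4_NUM / n) * r**4
    return float(out) if out.ndim == 0 else out


@dataclass
class DependenceModel:
    """Estimated dependence structure of the p-value sources."""

    rho_hat: np.ndarray
    n_pairs: np.ndarray
    rho_tilde: np.ndarray
    cov: np.ndarray
    source_names: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return int(self.cov.shape[0])


def build_dependence_model(p_matrix, *, min_complete: int = 3) -> DependenceModel:
    """Estimate correlations from a background panel and derive cov(V_i, V_j).

    The diagonal is fixed at exactly 4 = Var(chi2_2) so that independent
    sources reduce to the classical Fisher null.
    """
    df = pd.DataFrame(p_matrix)
    rho_hat, n_pairs = estimate_source_correlations(df, min_complete=min_complete)
    rho_tilde = shrink_correlation(rho_hat, n_pairs)
    cov = cov_minus2logp(rho_tilde, n_pairs)
    np.fill_diagonal(cov, 4.0)
    return DependenceModel(
        rho_hat=rho_hat,
        n_pairs=n_pairs,
        rho_tilde=rho_tilde,
        cov=cov,
        source_names=[str(c) for c in df.columns],
    )


def independent_dependence_model(k: int, source_names: Sequence[str] | None = None) -> DependenceModel:
    """A dependence model with all cross-source correlations fixed at zero."""
    names = list(source_names) if source_names is not None else [f"s{i}" for i in range(k)]
    eye = np.eye(k)
    return DependenceModel(
        rho_hat=eye.copy(),
        n_pairs=np.full((k, k), 0, dtype=np.int64),
        rho_tilde=eye.copy(),
        cov=4.0 * eye,
        source_names=names,
    )


@dataclass(frozen=True)
class BrownNull:
    """Scaled chi-squared null eta * chi2_v for the Fisher statistic U."""

    eta: float
    v: float

    def sf(self, u):
        """Upper-tail probability P(eta * chi2_v >= u)."""
        u = np.asarray(u, dtype=float)
        p = stats.chi2.sf(u / self.eta, df=self.v)
        p = np.clip(p, _P_FLOOR, 1.0)
        return float(p) if p.ndim == 0 else p


def brown_null(
    dep: DependenceModel,
    mask: Sequence[bool] | None = None,
    *,
    eta_floor: float = DEFAULT_ETA_FLOOR,
) -> BrownNull:
    """Moment-matched scaled-chi2 null over the present sources.

    With K present sources, E[U] = 2K and Var[U] = sum of the cov submatrix,
    giving eta = Var[U]/(4K) and v = 2K/eta. Under independence this is
    (eta, v) = (1, 2K); under perfect dependence (K, 2).
    """
    if mask is None:
        mask = np.ones(dep.k, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    k = int(mask.sum())
    if k == 0:
        raise MissingResultError("no present sources; cannot fit a combination null")
    idx = np.flatnonzero(mask)
    var_u = float(dep.cov[np.ix_(idx, idx)].sum())
    eta = var_u / (4.0 * k)
    if not np.isfinite(eta) or eta < eta_floor:
        logger.warning("non-positive Var(U); eta floored at %g", eta_floor)
        eta = eta_floor
    v = 2.0 * k / eta
    return BrownNull(eta=eta, v=v)


@dataclass
class PValueVector:
    """K p-values for one candidate, with per-source presence mask."""

    values: np.ndarray
    source_names: list[str] = field(default_factory=list)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        present = self.values[self.mask]
        if np.any(present <= 0.0) or np.any(present > 1.0):
            raise GlintsError("present p-values must lie in (0, 1]")
        if not self.source_names:
            self.source_names = [f"s{i}" for i in range(self.values.size)]


@dataclass
class CombinedResult:
    U: float
    p_combined: float
    k_effective: int
    q_value: float | None = None
    rank: int | None = None


def fisher_statistic(values: np.ndarray, mask: np.ndarray) -> float:
    """U = sum over present sources of -2 log p."""
    return float(-2.0 * np.log(values[mask]).sum())


def combine_pvalues(pv: PValueVector, null: BrownNull) -> CombinedResult:
    """Combine one p-value vector under a fitted scaled-chi2 null."""
    k = int(pv.mask.sum())
    if k == 0:
        raise MissingResultError("no present p-values to combine")
    u = fisher_statistic(pv.values, pv.mask)
    return CombinedResult(U=u, p_combined=null.sf(u), k_effective=k)


def combine_matrix(
    p_matrix,
    dep: DependenceModel | None = None,
    *,
    min_complete: int = 3,
    eta_floor: float = DEFAULT_ETA_FLOOR,
) -> pd.DataFrame:
    """Row-wise combination of a candidates x K p-value matrix.

    The dependence model defaults to one estimated from ``p_matrix`` itself
    (pairwise-complete). The scaled-chi2 null is re-fitted once per distinct
    missingness pattern and cached. Returns a frame with columns
    ``U``, ``p_combined``, ``k_effective``, ``eta``, ``v``.
    """
    df = pd.DataFrame(p_matrix).astype(float)
    if dep is None:
        dep = build_dependence_model(df, min_complete=min_complete)
    values = df.to_numpy()
    mask = np.isfinite(values)
    if not mask.any(axis=1).all():
        raise MissingResultError("some rows have no present p-values")
    with np.errstate(invalid="ignore"):
        if np.nanmin(values) <= 0.0 or np.nanmax(values) > 1.0:
            raise GlintsError("present p-values must lie in (0, 1]")
    logp = np.where(mask, np.log(np.where(mask, values, 1.0)), 0.0)
    U = -2.0 * logp.sum(axis=1)
    null_cache: dict[bytes, BrownNull] = {}
    out = np.empty((len(df), 4))
    for pattern in np.unique(mask, axis=0):
        key = pattern.tobytes()
        null = null_cache.setdefault(key, brown_null(dep, pattern, eta_floor=eta_floor))
        rows = np.flatnonzero((mask == pattern).all(axis=1))
        out[rows, 0] = null.sf(U[rows])
        out[rows, 1] = pattern.sum()
        out[rows, 2] = null.eta
        out[rows, 3] = null.v
    return pd.DataFrame(
        {
            "U": U,
            "p_combined": out[:, 0],
            "k_effective": out[:, 1].astype(int),
            "eta": out[:, 2],
            "v": out[:, 3],
        },
        index=df.index,
    )


# ---------------------------------------------------------------------------
# q-values (positive false discovery rate)
# ---------------------------------------------------------------------------

def estimate_pi0(
    p: np.ndarray, lambdas: np.ndarray | None = None
) -> float:
    """Storey smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed over the
    lambda grid, smoothed by a cubic polynomial and read off at the largest
    lambda; the result is clipped to [1/m, 1].
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    if m < 20:
        logger.warning("too few p-values (%d) for pi0 smoothing; using pi0 = 1", m)
        return 1.0
    pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    coeffs = np.polynomial.polynomial.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polynomial.polynomial.polyval(lambdas[-1], coeffs))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def compute_qvalues(
    p_combined,
    *,
    pi0: float | None = None,
    pi0_mode: str = "smoother",
) -> np.ndarray:
    """Storey q-values: q_i = pi0 * min_{p_j >= p_i} (p_j * m / rank_j).

    ``pi0_mode="fixed"`` (or an explicit ``pi0=1``) reduces exactly to
    Benjamini-Hochberg adjusted p-values.
    """
    p = np.asarray(p_combined, dtype=float)
    if p.size == 0:
        raise GlintsError("cannot compute q-values of an empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise GlintsError("q-value input p-values must lie in (0, 1]")
    if pi0 is None:
        if pi0_mode == "fixed":
            pi0 = 1.0
        elif pi0_mode == "smoother":
            pi0 = estimate_pi0(p)
        else:
            raise GlintsError(f"unknown pi0_mode {pi0_mode!r}")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(pi0 * q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
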