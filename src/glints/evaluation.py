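"""Spike-in benchmarking, ranking metrics and calibration experiments.

Metrics follow the rank-ratio family used for prioritization benchmarks:

* **rank ratio** -- the rank of a causal variant divided by the number of
  neutral variants it was ranked against;
* **MRR** -- the mean rank ratio over causal variants (smaller is better);
* **rank ROC AUC** -- the area under the curve obtained by sweeping a rank
  -ratio threshold (true-positive rate = fraction of causal ratios below it,
  false-positive rate = fraction of neutral ratios below it);
* **TOP** -- the number of causal variants ranked within the top k.

Causal ranks use conservative competition ranking: ties with neutral
variants count against the causal variant.

The module also hosts the reusable experiment drivers the acceptance checks
and tests are built on: independence reduction of the dependence-corrected
combination to classical Fisher, type-I calibration under an equicorrelated
copula, regression oracles, null uniformity, parameter recovery, empirical
-p self-consistency, q-value/BH agreement, the hypergeometric enrichment
oracle, and the end-to-end spike-in study.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import combination
from .exceptions import GlintsError
from .score_calibration import build_empirical_null, empirical_p_value
from .synthetic_data import Region, SyntheticWorld, WorldConfig, make_world, simulate_candidates
from .pipeline import (
    PipelineOptions,
    build_score_nulls,
    resources_from_world,
    run_prioritization,
)


# ---------------------------------------------------------------------------
# Rank metrics
# ---------------------------------------------------------------------------

@dataclass
class RankMetrics:
    rank_ratios: np.ndarray
    mrr: float
    auc: float
    top_k: int
    k: int
    n_neutral: int


def compute_rank_metrics(
    causal_ranks: Sequence[int], n_neutral: int, k: int = 10
) -> RankMetrics:
    """Rank-ratio metrics for spiked causal variants.

    Each causal rank is assumed to come from an independent spike-in run
    against ``n_neutral`` neutral variants; the neutral ranks of each run are
    therefore the remaining positions 1..n_neutral+1.
    """
    ranks = np.asarray(causal_ranks, dtype=int)
    if ranks.size == 0:
        raise GlintsError("no causal ranks given")
    if np.any(ranks < 1) or n_neutral < 1:
        raise GlintsError("ranks must be >= 1 and n_neutral >= 1")
    ratios = ranks / n_neutral
    all_positions = np.arange(1, n_neutral + 2)
    neutral_ratios = np.concatenate(
        [np.delete(all_positions, r - 1) / n_neutral for r in ranks]
    )
    from sklearn.metrics import roc_auc_score

    scores = np.concatenate([-ratios, -neutral_ratios])
    labels = np.concatenate(
        [np.ones(ratios.size), np.zeros(neutral_ratios.size)]
    )
    auc = float(roc_auc_score(labels, scores))
    return RankMetrics(
        rank_ratios=ratios,
        mrr=float(ratios.mean()),
        auc=auc,
        top_k=int((ranks <= k).sum()),
        k=k,
        n_neutral=n_neutral,
    )


def conservative_rank(causal_value: float, neutral_values: np.ndarray) -> int:
    """Competition rank of the causal value (ascending better); ties and a
    missing causal value count against the causal variant."""
    neutral = np.asarray(neutral_values, dtype=float)
    if not np.isfinite(causal_value):
        return neutral.size + 1
    finite = neutral[np.isfinite(neutral)]
    # missing neutral values rank behind everything
    return int((finite <= causal_value).sum()) + 1


def enrichment_p(N: int, K_func: int, n_top: int, x: int) -> float:
    """One-sided enrichment p of ``x`` functional variants in a top list.

    Upper tail P(X >= x) for X ~ Hypergeometric(N, K_func, n_top);
    equivalent to the one-sided Fisher exact test on the 2x2
    top/rest x functional/other table.
    """
    if not (0 <= K_func <= N and 0 <= n_top <= N):
        raise ValueError("need 0 <= K_func, n_top <= N")
    if not (0 <= x <= min(K_func, n_top)):
        raise ValueError(f"x = {x} outside [0, min(K_func, n_top)]")
    return float(stats.hypergeom.sf(x - 1, N, K_func, n_top))


# ---------------------------------------------------------------------------
# Experiment drivers
# ---------------------------------------------------------------------------

def fisher_reduction_experiment(
    seed: int = 0, n_grid: int = 1000, k_values: Sequence[int] = tuple(range(2, 18))
) -> float:
    """Max |combined p - classical Fisher chi2_{2K} p| with all rho fixed at 0."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for k in k_values:
        dep = combination.independent_dependence_model(k)
        null = combination.brown_null(dep)
        p = rng.uniform(1e-8, 1.0, size=(n_grid, k))
        u = -2.0 * np.log(p).sum(axis=1)
        ours = null.sf(u)
        classical = stats.chi2.sf(u, df=2 * k)
        worst = max(worst, float(np.abs(ours - classical).max()))
    return worst


def brown_calibration_experiment(
    seed: int = 0,
    n_draws: int = 20000,
    k: int = 10,
    rho: float = 0.6,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Type-I error of the corrected vs naive Fisher combination under an
    equicorrelated Gaussian copula null."""
    from .synthetic_data import equicorrelation, _copula_root

    rng = np.random.default_rng(seed)
    root = _copula_root(equicorrelation(k, rho))
    z = rng.standard_normal((n_draws, k)) @ root.T
    p = stats.norm.sf(z)
    df = pd.DataFrame(p, columns=[f"s{i}" for i in range(k)])
    dep = combination.build_dependence_model(df)
    null = combination.brown_null(dep)
    u = -2.0 * np.log(p).sum(axis=1)
    return {
        "brown_rejection_rate": float((null.sf(u) < alpha).mean()),
        "naive_fisher_rejection_rate": float(
            (stats.chi2.sf(u, df=2 * k) < alpha).mean()
        ),
        "alpha": alpha,
        "eta": null.eta,
        "v": null.v,
    }


def _simulate_regression_dataset(rng, n, p, alpha, beta, noise_sd=1.0):
    from .association_regression import RegressionInputs

    x = rng.standard_normal(n)
    Y = alpha + np.outer(x, beta) + noise_sd * rng.standard_normal((n, p))
    return RegressionInputs(
        Y=Y, x=x, row_ids=[f"d{i}" for i in range(n)],
        response_names=[f"y{j}" for j in range(p)],
    )


def regression_oracle_experiment(
    seed: int = 0, n_datasets: int = 500, n: int = 20, p: int = 3
) -> dict[str, float]:
    """Agreement of the multivariate fit/test with per-response textbook
    least squares when lambda is a coordinate basis vector."""
    from .association_regression import association_test, fit_mle

    rng = np.random.default_rng(seed)
    worst_t = worst_beta = 0.0
    for _ in range(n_datasets):
        inputs = _simulate_regression_dataset(
            rng, n, p, rng.normal(size=p), rng.normal(size=p)
        )
        fit = fit_mle(inputs)
        x, Y = inputs.x, inputs.Y
        xc = x - x.mean()
        sxx = xc @ xc
        for j in range(p):
            y = Y[:, j]
            # textbook simple-regression slope and t statistic
            b = float(xc @ (y - y.mean()) / sxx)
            resid = (y - y.mean()) - b * xc
            se = math.sqrt(float(resid @ resid) / (n - 2) / sxx)
            t_oracle = b / se
            lam = np.zeros(p)
            lam[j] = 1.0
            result = association_test(fit, inputs, lam=lam)
            worst_t = max(worst_t, abs(result.T - t_oracle))
            worst_beta = max(worst_beta, abs(float(fit.beta_hat[j]) - b))
    return {"max_t_error": worst_t, "max_beta_error": worst_beta}


def null_uniformity_experiment(
    seed: int = 0, n_datasets: int = 2000, n: int = 50, p: int = 3
) -> dict[str, float]:
    """KS test of association p-values against Uniform(0,1) under beta = 0."""
    from .association_regression import association_test, fit_mle

    rng = np.random.default_rng(seed)
    pvals = np.empty(n_datasets)
    for i in range(n_datasets):
        inputs = _simulate_regression_dataset(
            rng, n, p, rng.normal(size=p), np.zeros(p)
        )
        fit = fit_mle(inputs)
        pvals[i] = association_test(fit, inputs).p_analytical
    ks = stats.kstest(pvals, "uniform")
    return {"ks_statistic": float(ks.statistic), "ks_pvalue": float(ks.pvalue)}


def parameter_recovery_experiment(
    seed: int = 0,
    n_reps: int = 500,
    n: int = 50,
    p: int = 3,
    alpha: Sequence[float] = (0.5, -0.2, 1.0),
    beta: Sequence[float] = (0.8, 0.3, -0.5),
) -> dict[str, float]:
    """Fraction of coefficient estimates within 3 standard errors of truth,
    pooled over the 2p coefficients and all replicates."""
    from .association_regression import fit_mle

    rng = np.random.default_rng(seed)
    alpha = np.asarray(alpha, dtype=float)[:p]
    beta = np.asarray(beta, dtype=float)[:p]
    hits = total = 0
    for _ in range(n_reps):
        inputs = _simulate_regression_dataset(rng, n, p, alpha, beta)
        fit = fit_mle(inputs)
        sxx = fit.xtx_c
        sig = np.diag(fit.sigma_eps_hat)
        se_beta = np.sqrt(sig / sxx)
        se_alpha = np.sqrt(sig * (1.0 / n + fit.x_bar**2 / sxx))
        hits += int((np.abs(fit.beta_hat - beta) <= 3 * se_beta).sum())
        hits += int((np.abs(fit.alpha_hat - alpha) <= 3 * se_alpha).sum())
        total += 2 * p
    return {"coverage_3se": hits / total, "n_coefficients": total}


def calibration_selfconsistency_experiment(
    seed: int = 0, n: int = 5000, n_panel: int = 50000
) -> dict[str, float]:
    """Empirical p-values of scores drawn from their own null should be
    uniform; returns the KS test against Uniform(0,1).

    The null panel is drawn an order of magnitude larger than the query set,
    matching the database-scale panels the calibration is designed for --
    a same-size panel would add a common empirical-CDF error to every query
    p-value and the KS test (which assumes independence) would overstate the
    discrepancy.
    """
    rng = np.random.default_rng(seed)
    null = build_empirical_null(
        rng.standard_normal(n_panel), score_name="self", min_n=10
    )
    queries = rng.standard_normal(n)
    p = empirical_p_value(null, queries)
    ks = stats.kstest(p, "uniform")
    return {"ks_statistic": float(ks.statistic), "ks_pvalue": float(ks.pvalue)}


def qvalue_bh_experiment(seed: int = 0, m: int = 10000) -> float:
    """Max |q(pi0=1) - Benjamini-Hochberg adjusted p| on random inputs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for size in (1, 3, 100, m):
        p = rng.uniform(np.nextafter(0.0, 1.0), 1.0, size=size)
        q = combination.compute_qvalues(p, pi0_mode="fixed")
        # independent BH step-up oracle
        order = np.argsort(p)
        adj = np.empty(size)
        running = 1.0
        for i in range(size - 1, -1, -1):
            running = min(running, p[order[i]] * size / (i + 1))
            adj[order[i]] = running
        worst = max(worst, float(np.abs(q - adj).max()))
    return worst


def hypergeometric_oracle_experiment(max_N: int = 12) -> float:
    """Max |enrichment_p - exhaustive enumeration| over all N <= max_N."""
    worst = 0.0
    for N in range(1, max_N + 1):
        items = np.arange(N)
        for K_func in range(0, N + 1):
            functional = set(range(K_func))
            for n_top in range(0, N + 1):
                tops = list(itertools.combinations(items, n_top))
                counts = np.array([len(functional & set(t)) for t in tops])
                for x in range(0, min(K_func, n_top) + 1):
                    exact = float((counts >= x).mean())
                    worst = max(worst, abs(enrichment_p(N, K_func, n_top, x) - exact))
    return worst


# ---------------------------------------------------------------------------
# End-to-end spike-in study
# ---------------------------------------------------------------------------

def spike_in_study(
    seed: int = 0,
    n_runs: int = 50,
    n_neutral: int = 500,
    region: Region = Region.EXON,
    world: SyntheticWorld | None = None,
    config: WorldConfig | None = None,
    k_top: int = 10,
) -> dict:
    """Repeated spike-in runs of the full pipeline on a synthetic world.

    Each run spikes one causal variant into a fresh pool of ``n_neutral``
    controls from the same region, runs the prioritization end to end and
    records the causal variant's conservative rank -- both for the combined
    ranking and for every single source ranked on its own (missing values
    rank last). Returns the pooled metrics and the per-source MRRs.
    """
    rng = np.random.default_rng(seed)
    if world is None:
        world = make_world(int(rng.integers(0, 2**31 - 1)), config)
    resources = resources_from_world(world)
    resources.score_nulls = build_score_nulls(resources)
    options = PipelineOptions()
    disease = world.truth["query_disease"]

    causal_pool = world.causal_keys(region)
    causal_keys = [
        str(causal_pool[i % len(causal_pool)]) for i in range(n_runs)
    ]
    combined_ranks = []
    source_ranks: dict[str, list[int]] = {}
    for run, causal_key in enumerate(causal_keys):
        candidates = simulate_candidates(
            world, region, n_neutral,
            seed=int(rng.integers(0, 2**31 - 1)),
            causal_key=causal_key,
        )
        result = run_prioritization(candidates.variants, disease, resources, options)
        ranked = result.ranked.set_index("variant_key")
        if causal_key not in ranked.index:
            combined_ranks.append(n_neutral + 1)
        else:
            causal_p = float(ranked.loc[causal_key, "p_combined"])
            neutral_p = ranked.loc[ranked.index != causal_key, "p_combined"].to_numpy()
            combined_ranks.append(conservative_rank(causal_p, neutral_p))
        for src in result.source_names:
            col = ranked[src]
            causal_v = float(col.get(causal_key, np.nan))
            neutral_v = col[col.index != causal_key].to_numpy(dtype=float)
            source_ranks.setdefault(src, []).append(
                conservative_rank(causal_v, neutral_v)
            )

    metrics = compute_rank_metrics(combined_ranks, n_neutral, k=k_top)
    per_source_mrr = {
        src: float(np.mean(np.asarray(r) / n_neutral))
        for src, r in source_ranks.items()
    }
    best_source = min(per_source_mrr, key=per_source_mrr.get)
    return {
        "mrr": metrics.mrr,
        "auc": metrics.auc,
        "top_k": metrics.top_k,
        "k": k_top,
        "n_runs": n_runs,
        "n_neutral": n_neutral,
        "region": Region(region).value,
        "combined_ranks": combined_ranks,
        "per_source_mrr": per_source_mrr,
        "best_single_source": best_source,
        "best_single_source_mrr": per_source_mrr[best_source],
    }
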