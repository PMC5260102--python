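"""End-to-end prioritization: annotate, calibrate, associate, combine, rank.

``run_prioritization`` takes candidate SNVs and a query disease plus a
resource bundle (gene models, reference genome, background score database,
gene/phenotype similarity spaces) and produces one ranked row per retained
variant: all per-source empirical p-values, the Fisher statistic U, the
dependence-corrected combined p-value, the pFDR q-value and the rank.
Discarded variants (intergenic, synonymous, deep-intronic) are reported in a
sidecar table with the reason.

Variant-level sources are the region-applicable functional scores; gene-level
sources are the calibrated association p-values of the host gene, computed
once per (gene, disease) and shared by all that gene's variants. A variant
overlapping several genes is scored against each and keeps the best (smallest
combined p) gene; all pairs remain available for audit.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import combination
from .association_regression import (
    DiseaseSpace,
    GeneSimilarityMeasure,
    gene_association_pvalues,
)
from .exceptions import GlintsError
from .score_calibration import (
    NullScoreDistribution,
    ScoreDefinition,
    build_empirical_null,
    build_score_panel,
    calibrate_gene_p,
    default_score_registry,
)
from .variant_annotation import (
    DEFAULT_PROMOTER_WINDOW,
    GenomicVariant,
    Region,
    TranscriptModel,
    classify_variant_all,
)

logger = logging.getLogger(__name__)

GENE_SOURCE_PREFIX = "gene_"


@dataclass
class PipelineResources:
    """Everything the pipeline loads once and reuses across variants."""

    transcripts: list[TranscriptModel]
    genome: Mapping[str, str] | object
    score_table: pd.DataFrame                 # raw scores, key-indexed
    space: DiseaseSpace
    measures: dict[str, GeneSimilarityMeasure]
    neutral_genes: list[str]                  # never disease-associated
    known_causal_keys: frozenset[str] = frozenset()
    score_registry: dict[str, ScoreDefinition] = field(
        default_factory=default_score_registry
    )
    score_nulls: dict[str, NullScoreDistribution] | None = None


@dataclass
class PipelineOptions:
    promoter_window: int = DEFAULT_PROMOTER_WINDOW
    count_stop_changes: bool = True
    leave_out: bool = True
    lam: Sequence[float] | None = None
    min_null: int = 100
    pi0_mode: str = "smoother"
    eta_floor: float = combination.DEFAULT_ETA_FLOOR
    min_complete: int = 3


@dataclass
class PrioritizationResult:
    ranked: pd.DataFrame        # one row per retained variant (best gene)
    discarded: pd.DataFrame     # variant_key, reason
    per_gene: pd.DataFrame      # all (variant, gene) rows
    gene_pvalues: pd.DataFrame  # calibrated gene-level p per measure
    source_names: list[str]


def resources_from_world(world) -> PipelineResources:
    """Build a resource bundle from a :class:`~glints.synthetic_data.SyntheticWorld`."""
    return PipelineResources(
        transcripts=world.transcripts,
        genome=world.genome,
        score_table=world.score_table,
        space=world.space,
        measures=world.measures,
        neutral_genes=world.neutral_genes,
        known_causal_keys=world.known_causal_keys,
    )


def build_score_nulls(
    resources: PipelineResources, min_n: int = 100
) -> dict[str, NullScoreDistribution]:
    """Empirical null panels per score from the background database,
    known causal variants excluded, whole-database (all regions) by default."""
    from .score_calibration import orient_table

    oriented = orient_table(resources.score_table, resources.score_registry)
    return {
        name: build_empirical_null(
            oriented[name],
            exclude=resources.known_causal_keys,
            score_name=name,
            min_n=min_n,
        )
        for name in oriented.columns
    }


def compute_gene_pvalues(
    genes: Sequence[str],
    disease: str,
    resources: PipelineResources,
    options: PipelineOptions,
) -> pd.DataFrame:
    """Calibrated gene-level association p-values for ``genes``.

    Analytical p-values are computed per measure; a per-measure empirical
    null is built from the analytical p-values of the neutral genes, and
    the candidates are calibrated against it.
    """
    space, measures = resources.space, resources.measures
    null_analytical = {
        g: gene_association_pvalues(
            g, disease, space, measures, lam=options.lam, leave_out=options.leave_out
        )
        for g in resources.neutral_genes
    }
    null_df = pd.DataFrame(null_analytical).T  # neutral genes x measures
    analytical = {
        g: gene_association_pvalues(
            g, disease, space, measures, lam=options.lam, leave_out=options.leave_out
        )
        for g in genes
    }
    analytical_df = pd.DataFrame(analytical).T
    calibrated = {}
    for m in measures:
        null_ps = null_df[m].dropna().to_numpy()
        col = analytical_df[m].to_numpy()
        if null_ps.size == 0:
            logger.warning("no neutral-gene null for measure %s; gene p missing", m)
            calibrated[m] = np.full(col.shape, np.nan)
            continue
        out = np.full(col.shape, np.nan)
        present = np.isfinite(col)
        if present.any():
            out[present] = calibrate_gene_p(null_ps, col[present])
        calibrated[m] = out
    return pd.DataFrame(calibrated, index=analytical_df.index)


def run_prioritization(
    variants: Sequence[GenomicVariant],
    disease: str,
    resources: PipelineResources,
    options: PipelineOptions | None = None,
) -> PrioritizationResult:
    """Rank candidate SNVs by combined variant- and gene-level evidence."""
    options = options or PipelineOptions()
    space = resources.space
    if disease not in space.diseases:
        near = difflib.get_close_matches(disease, space.diseases, n=3)
        raise GlintsError(
            f"unknown disease {disease!r}; nearest identifiers: {near or 'none'}"
        )

    # ---- step 1: region classification ----------------------------------
    assignments = []   # (variant, region, gene, detail)
    discarded = []
    for v in variants:
        hits = classify_variant_all(
            v, resources.transcripts, resources.genome,
            promoter_window=options.promoter_window,
            count_stop_changes=options.count_stop_changes,
        )
        if not hits:
            discarded.append({"variant_key": v.key, "reason": "no_region"})
            continue
        for a in hits:
            assignments.append(
                {
                    "variant_key": v.key, "chrom": v.chrom, "pos": v.pos,
                    "ref": v.ref, "alt": v.alt,
                    "region": a.region.value, "gene_id": a.gene_id,
                    "detail": a.detail,
                }
            )
    discarded_df = pd.DataFrame(discarded, columns=["variant_key", "reason"])
    if not assignments:
        logger.warning("no retained variants; output is empty")
        empty = pd.DataFrame()
        return PrioritizationResult(empty, discarded_df, empty, empty, [])
    pairs = pd.DataFrame(assignments)

    # ---- step 2: variant-level empirical p-values -----------------------
    nulls = resources.score_nulls or build_score_nulls(resources, options.min_null)
    unique = pairs.drop_duplicates("variant_key").set_index("variant_key")
    # region per variant for applicability: most severe assignment wins
    panel = build_score_panel(
        resources.score_table.reindex(unique.index),
        unique["region"],
        nulls,
        resources.score_registry,
    )
    variant_p = panel.pvalues

    # ---- step 3: gene-level calibrated p-values -------------------------
    genes = sorted(set(pairs["gene_id"]))
    gene_p = compute_gene_pvalues(genes, disease, resources, options)
    gene_p = gene_p.rename(columns=lambda m: f"{GENE_SOURCE_PREFIX}{m}")

    # ---- step 4: assemble and combine -----------------------------------
    source_names = list(variant_p.columns) + list(gene_p.columns)
    p_matrix = pd.concat(
        [
            variant_p.reindex(pairs["variant_key"]).reset_index(drop=True),
            gene_p.reindex(pairs["gene_id"]).reset_index(drop=True),
        ],
        axis=1,
    )
    p_matrix.index = pairs.index
    present_any = p_matrix.notna().any(axis=1)
    if not present_any.all():
        dropped = pairs.loc[~present_any, "variant_key"].unique()
        logger.warning("%d (variant, gene) rows with no sources dropped", len(dropped))
    combined = combination.combine_matrix(
        p_matrix[present_any],
        min_complete=options.min_complete,
        eta_floor=options.eta_floor,
    )
    per_gene = pd.concat([pairs[present_any], p_matrix[present_any], combined], axis=1)

    # keep the best (smallest combined p, then larger U) gene per variant
    per_gene_sorted = per_gene.sort_values(
        ["p_combined", "U", "gene_id"], ascending=[True, False, True], kind="mergesort"
    )
    best = per_gene_sorted.drop_duplicates("variant_key").copy()

    lost = set(pairs["variant_key"]) - set(best["variant_key"])
    for key in sorted(lost):
        discarded_df.loc[len(discarded_df)] = [key, "no_p_value_source"]

    best["q_value"] = combination.compute_qvalues(
        best["p_combined"].to_numpy(), pi0_mode=options.pi0_mode
    )
    best = best.sort_values(
        ["p_combined", "U", "variant_key"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    best["rank"] = np.arange(1, len(best) + 1)

    return PrioritizationResult(
        ranked=best,
        discarded=discarded_df,
        per_gene=per_gene.reset_index(drop=True),
        gene_pvalues=gene_p,
        source_names=source_names,
    )
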