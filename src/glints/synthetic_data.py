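"""Synthetic worlds for desk-scale spike-in experiments.

Every input the prioritization pipeline consumes can be generated here from a
single seed: a toy genome with multi-exon gene models, a correlated
functional-score database with planted causal enrichment, a disease space
with a planted gene-disease association signal, and candidate variant sets
with one spiked causal variant per run.

Generative model, in brief:

* **Scores.** Oriented score values follow a Gaussian copula with a target
  K x K correlation matrix (default: equicorrelation 0.4 across the 14
  sources, in the range of the pairwise Pearson correlations real
  deleteriousness predictors show). Causal variants receive a +1.5 SD mean
  shift on every applicable source, giving each source a standalone
  rank-ROC AUC of about 0.86. Marginals are standardized; unit-interval
  LOWER_WORSE scores (SIFT, LRT) are stored as 1 - Phi(z) so that their
  declared orientation holds. Missingness is injected per source.

* **Diseases.** Genes live in a latent Euclidean embedding; functional
  similarity is phi0 = exp(-d^2 / (2 s^2)), and each of the nine released
  measures is phi0 plus symmetric noise. Each disease carries a small gene
  set; phenotype similarities are generated from the regression model
  y = a + b * x + e with x the true genotype similarity, then truncated to
  [0, 1]. The query disease's causal genes enter the generative step but are
  withheld from the released disease->gene map.

* **Candidates.** A spike-in draw is n_neutral control SNVs from the
  requested region class plus one causal SNV hosted by a causal gene; exonic
  draws are guaranteed nonsynonymous so the annotation step retains them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association_regression import DiseaseSpace, GeneSimilarityMeasure
from .exceptions import GlintsError, ValidationError
from .score_calibration import (
    Direction,
    ScoreDefinition,
    default_score_registry,
)
from .variant_annotation import (
    GenomicVariant,
    Region,
    TranscriptModel,
    fetch_sequence,
)

_BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Field-standard abbreviations for the nine gene-similarity measures.
DEFAULT_MEASURE_NAMES = (
    "gexp", "gobp", "kegg", "mrna", "pfam", "pseq", "sign", "strg", "tsfc",
)
DEFAULT_PHENOTYPE_MEASURES = ("UMLS", "MeSH", "HPO")

SPIKE_REGIONS = (Region.EXON, Region.PROMOTER, Region.INTRON, Region.SPLICE_SITE)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WorldConfig:
    """Study conditions of the synthetic world (defaults are the conditions
    used throughout the package's experiments)."""

    # gene models
    n_genes: int = 80
    n_exons: int = 4
    exon_len: int = 120
    intron_len: int = 300
    utr_len: int = 30
    gene_spacing: int = 2500
    # score database; None = the block-structured default correlations,
    # a float = equicorrelation at that value
    score_corr: float | None = None
    causal_shift: float = 1.5
    missing_rate_genome: float = 0.05
    missing_rate_protein: float = 0.15
    n_pool: Mapping[str, int] = field(
        default_factory=lambda: {
            Region.EXON.value: 1200,
            Region.PROMOTER.value: 800,
            Region.INTRON.value: 800,
            Region.SPLICE_SITE.value: 600,
        }
    )
    n_causal_per_region: int = 50
    # disease space
    n_diseases: int = 40
    n_causal_genes: int = 5
    n_neutral_genes: int = 30
    genes_per_disease: tuple[int, int] = (1, 3)
    embedding_dim: int = 3
    embedding_scale: float = 1.0
    n_measures: int = 9
    measure_noise_sd: float = 0.05
    intercept: float = 0.30
    slope: float = 0.08
    noise_sd: float = 0.10
    noise_corr: float = 0.3


SMALL_CONFIG = WorldConfig(
    n_genes=30,
    n_pool={
        Region.EXON.value: 300,
        Region.PROMOTER.value: 250,
        Region.INTRON.value: 250,
        Region.SPLICE_SITE.value: 200,
    },
    n_causal_per_region=10,
    n_diseases=20,
    n_causal_genes=3,
    n_neutral_genes=10,
)

PRESETS = {"small": SMALL_CONFIG, "medium": WorldConfig()}


# ---------------------------------------------------------------------------
# Toy genome and gene models
# ---------------------------------------------------------------------------

def toy_gene_models(
    rng: np.random.Generator, config: WorldConfig, chrom: str = "chr1"
) -> tuple[dict[str, str], list[TranscriptModel]]:
    """A random genome string plus evenly spaced multi-exon transcripts."""
    length = 1000 + config.n_genes * config.gene_spacing + 1000
    seq = _BASE_BYTES[rng.integers(0, 4, size=length)].tobytes().decode()
    genome = {chrom: seq}
    transcripts = []
    for i in range(config.n_genes):
        start = 1000 + i * config.gene_spacing
        exons = []
        pos = start
        for _ in range(config.n_exons):
            exons.append((pos, pos + config.exon_len))
            pos += config.exon_len + config.intron_len
        end = exons[-1][1]
        transcripts.append(
            TranscriptModel(
                gene_id=f"G{i:03d}",
                chrom=chrom,
                strand="+" if i % 2 == 0 else "-",
                exons=tuple(exons),
                cds_start=start + config.utr_len,
                cds_end=end - config.utr_len,
                transcript_id=f"G{i:03d}.t1",
            )
        )
    return genome, transcripts


def _region_positions(t: TranscriptModel, promoter_window: int = 500) -> dict[Region, list[int]]:
    """Candidate 0-based positions per region class for one transcript."""
    out: dict[Region, list[int]] = {r: [] for r in SPIKE_REGIONS}
    out[Region.EXON] = list(t.coding_positions)
    for s, e in t.introns:
        out[Region.SPLICE_SITE] += [s, s + 1, e - 2, e - 1]
        out[Region.INTRON] += list(range(s + 2, s + 10)) + list(range(e - 10, e - 2))
    for intervals in t.utr_intervals.values():
        for s, e in intervals:
            out[Region.PROMOTER] += list(range(s, e))
    if t.strand == "+":
        out[Region.PROMOTER] += list(range(t.start - promoter_window, t.start))
    else:
        out[Region.PROMOTER] += list(range(t.end, t.end + promoter_window))
    return out


def _pick_alt(
    rng: np.random.Generator,
    genome: Mapping[str, str],
    t: TranscriptModel,
    pos0: int,
    region: Region,
) -> tuple[str, str] | None:
    """Pick (ref, alt) at a position; for EXON, the alt must be nonsynonymous."""
    from .variant_annotation import is_nonsynonymous

    ref = fetch_sequence(genome, t.chrom, pos0, pos0 + 1)
    alts = [b for b in _BASES if b != ref]
    rng.shuffle(alts)
    if region is not Region.EXON:
        return ref, alts[0]
    for alt in alts:
        v = GenomicVariant(chrom=t.chrom, pos=pos0 + 1, ref=ref, alt=alt)
        changed, _ = is_nonsynonymous(v, t, genome)
        if changed:
            return ref, alt
    return None


# ---------------------------------------------------------------------------
# Score database
# ---------------------------------------------------------------------------

def _copula_root(corr: np.ndarray) -> np.ndarray:
    """Matrix square root of a correlation matrix; rejects non-PSD input."""
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise GlintsError("correlation matrix must be square")
    vals, vecs = np.linalg.eigh((corr + corr.T) / 2.0)
    if vals.min() < -1e-8:
        raise GlintsError(
            f"target correlation matrix is not positive semidefinite "
            f"(min eigenvalue {vals.min():.3g})"
        )
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def equicorrelation(k: int, rho: float) -> np.ndarray:
    return np.full((k, k), rho) + (1.0 - rho) * np.eye(k)


#: Two-factor loadings behind the default inter-score correlation structure:
#: a conservation factor (alignment-based scores cluster tightly, SiPhy is
#: nearly independent of everything) and an ensemble/protein factor (the
#: supervised integrative scores and the protein-level predictors). The
#: implied correlations are high within each cluster and low across, the
#: pattern real deleteriousness predictors exhibit.
SCORE_FACTOR_LOADINGS: dict[str, tuple[float, float]] = {
    "CADD": (0.20, 0.55),
    "DANN": (0.15, 0.50),
    "FATHMM-MKL": (0.85, 0.10),
    "Eigen": (0.50, 0.50),
    "GERP": (0.70, 0.10),
    "phastCons": (0.85, 0.10),
    "SiPhy": (0.15, 0.05),
    "PhyloP": (0.70, 0.10),
    "MutationAssessor": (0.15, 0.60),
    "SIFT": (0.10, 0.45),
    "LRT": (0.40, 0.20),
    "MSRV": (0.15, 0.50),
    "PolyPhen2": (0.15, 0.60),
    "SinBaD": (0.50, 0.20),
}


def default_score_correlation(source_names: Sequence[str]) -> np.ndarray:
    """Block-structured correlation matrix implied by the factor loadings.

    corr = L L' off the diagonal, 1 on it -- positive semidefinite by
    construction. Unknown sources get zero loadings (independent).
    """
    L = np.array(
        [SCORE_FACTOR_LOADINGS.get(name, (0.0, 0.0)) for name in source_names]
    )
    corr = L @ L.T
    np.fill_diagonal(corr, 1.0)
    return corr


def _draw_oriented(
    rng: np.random.Generator,
    n_neutral: int,
    n_causal: int,
    corr: np.ndarray,
    shift: np.ndarray,
) -> np.ndarray:
    root = _copula_root(corr)
    z = rng.standard_normal((n_neutral + n_causal, corr.shape[0])) @ root.T
    if n_causal:
        z[n_neutral:] += shift
    return z


def _to_raw(
    oriented: np.ndarray,
    source_names: Sequence[str],
    registry: Mapping[str, ScoreDefinition],
) -> np.ndarray:
    """Map oriented copula values to each source's declared raw scale."""
    from scipy.stats import norm

    raw = oriented.copy()
    for j, name in enumerate(source_names):
        definition = registry.get(name)
        if definition is None or definition.direction is Direction.HIGHER_WORSE:
            continue
        if definition.unit_interval:
            raw[:, j] = norm.sf(oriented[:, j])  # 1 - Phi(z): smaller = worse
        else:
            raw[:, j] = -oriented[:, j]
    return raw


def simulate_score_database(
    n_variants: int,
    corr: np.ndarray | None = None,
    causal_shift: float | Sequence[float] = 0.0,
    seed: int = 0,
    *,
    n_causal: int = 0,
    source_names: Sequence[str] | None = None,
    missing_rates: Mapping[str, float] | float | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Standalone correlated score table with ``n_causal`` shifted variants.

    Returns ``(scores, causal_keys)``; the causal rows are the last
    ``n_causal`` rows. ``n_variants`` counts neutral rows.
    """
    registry = default_score_registry()
    if source_names is None:
        source_names = list(registry)
    k = len(source_names)
    if corr is None:
        corr = np.eye(k)
    shift = np.broadcast_to(np.asarray(causal_shift, dtype=float), (k,))
    rng = np.random.default_rng(seed)
    oriented = _draw_oriented(rng, n_variants, n_causal, np.asarray(corr), shift)
    raw = _to_raw(oriented, source_names, registry)
    if missing_rates is not None:
        for j, name in enumerate(source_names):
            rate = (
                missing_rates
                if np.isscalar(missing_rates)
                else missing_rates.get(name, 0.0)
            )
            if rate:
                raw[rng.random(raw.shape[0]) < rate, j] = np.nan
    keys = [f"snv_{i:06d}" for i in range(raw.shape[0])]
    scores = pd.DataFrame(raw, index=keys, columns=list(source_names))
    return scores, keys[n_variants:]


# ---------------------------------------------------------------------------
# Disease space
# ---------------------------------------------------------------------------

def simulate_disease_space(
    n_diseases: int = 40,
    n_genes: int = 80,
    slope: float | Sequence[float] = 0.08,
    noise_sd: float = 0.10,
    seed: int = 0,
    *,
    gene_names: Sequence[str] | None = None,
    n_causal_genes: int = 5,
    n_neutral_genes: int = 30,
    genes_per_disease: tuple[int, int] = (1, 3),
    embedding_dim: int = 3,
    embedding_scale: float = 1.0,
    n_measures: int = 9,
    measure_noise_sd: float = 0.05,
    intercept: float = 0.30,
    noise_corr: float = 0.3,
    phenotype_measure_names: Sequence[str] = DEFAULT_PHENOTYPE_MEASURES,
    measure_names: Sequence[str] | None = None,
) -> tuple[DiseaseSpace, dict[str, GeneSimilarityMeasure], dict]:
    """Disease space with a planted gene-disease association signal.

    Returns ``(space, measures, truth)``. The first disease is the query;
    its (causal) gene set enters the phenotype-similarity generation but is
    withheld from the released disease->gene map. ``truth`` records the
    query disease, the causal and neutral gene lists and the full true map.
    """
    if n_diseases < 10:
        raise ValidationError("need at least 10 diseases for a usable space")
    rng = np.random.default_rng(seed)
    if gene_names is None:
        gene_names = [f"G{i:03d}" for i in range(n_genes)]
    gene_names = list(gene_names)
    if len(gene_names) != n_genes:
        raise ValidationError("gene_names length must equal n_genes")
    if n_causal_genes + n_neutral_genes >= n_genes:
        raise ValidationError("need associable genes beyond causal + neutral sets")

    perm = list(rng.permutation(gene_names))
    causal_genes = perm[:n_causal_genes]
    neutral_genes = perm[n_causal_genes : n_causal_genes + n_neutral_genes]
    associable = perm[n_causal_genes + n_neutral_genes :]

    # Latent embedding -> base similarity phi0 and nine noisy measures.
    emb = rng.standard_normal((n_genes, embedding_dim))
    sq = ((emb[:, None, :] - emb[None, :, :]) ** 2).sum(axis=2)
    phi0 = np.exp(-sq / (2.0 * embedding_scale**2))
    if measure_names is None:
        measure_names = list(DEFAULT_MEASURE_NAMES[:n_measures])
    measures = {}
    for name in measure_names:
        noise = rng.normal(0.0, measure_noise_sd, size=phi0.shape)
        noisy = np.clip(phi0 + (noise + noise.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(noisy, 1.0)
        measures[name] = GeneSimilarityMeasure(
            name=name, phi=pd.DataFrame(noisy, index=gene_names, columns=gene_names)
        )

    diseases = [f"D{i:03d}" for i in range(n_diseases)]
    query = diseases[0]
    true_map: dict[str, frozenset[str]] = {query: frozenset(causal_genes)}
    lo, hi = genes_per_disease
    for d in diseases[1:]:
        size = int(rng.integers(lo, hi + 1))
        true_map[d] = frozenset(rng.choice(associable, size=size, replace=False))

    # True genotype similarities X = A phi0 A' over disease gene sets.
    gene_index = {g: i for i, g in enumerate(gene_names)}
    A = np.zeros((n_diseases, n_genes))
    for i, d in enumerate(diseases):
        for g in true_map[d]:
            A[i, gene_index[g]] = 1.0
    x_true = A @ phi0 @ A.T
    off = x_true[~np.eye(n_diseases, dtype=bool)]
    if np.ptp(off) <= 0.0:
        raise GlintsError("degenerate disease space: all genotype similarities equal")

    p = len(phenotype_measure_names)
    slopes = np.broadcast_to(np.asarray(slope, dtype=float), (p,))
    noise_cov = (noise_sd**2) * equicorrelation(p, noise_corr)
    noise_root = _copula_root(noise_cov / noise_sd**2) * noise_sd
    iu = np.triu_indices(n_diseases, k=1)
    eps = rng.standard_normal((iu[0].size, p)) @ noise_root.T
    sims = {}
    for j, name in enumerate(phenotype_measure_names):
        mat = np.eye(n_diseases)
        vals = np.clip(intercept + slopes[j] * x_true[iu] + eps[:, j], 0.0, 1.0)
        mat[iu] = vals
        mat = mat + mat.T - np.diag(np.diag(mat))
        np.fill_diagonal(mat, 1.0)
        sims[name] = pd.DataFrame(mat, index=diseases, columns=diseases)

    released = {d: true_map[d] for d in diseases[1:]}
    space = DiseaseSpace(
        diseases=diseases, phenotype_sims=sims, disease_genes=released
    )
    truth = {
        "query_disease": query,
        "causal_genes": causal_genes,
        "neutral_genes": neutral_genes,
        "true_disease_genes": {d: sorted(g) for d, g in true_map.items()},
        "slope": slopes.tolist(),
        "noise_sd": noise_sd,
        "intercept": intercept,
    }
    return space, measures, truth


# ---------------------------------------------------------------------------
# Whole worlds
# ---------------------------------------------------------------------------

@dataclass
class SyntheticWorld:
    """Everything the pipeline needs, reproducible from one seed."""

    seed: int
    config: WorldConfig
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    score_table: pd.DataFrame
    variant_meta: pd.DataFrame       # key-indexed: chrom,pos,ref,alt,region,gene_id,causal
    space: DiseaseSpace
    measures: dict[str, GeneSimilarityMeasure]
    neutral_genes: list[str]
    truth: dict

    @property
    def known_causal_keys(self) -> frozenset[str]:
        return frozenset(self.variant_meta.index[self.variant_meta["causal"]])

    def causal_keys(self, region: Region) -> list[str]:
        m = self.variant_meta
        return list(m.index[m["causal"] & (m["region"] == region.value)])

    def neutral_keys(self, region: Region) -> list[str]:
        m = self.variant_meta
        return list(m.index[~m["causal"] & (m["region"] == region.value)])

    def variant(self, key: str) -> GenomicVariant:
        row = self.variant_meta.loc[key]
        return GenomicVariant(
            chrom=row["chrom"], pos=int(row["pos"]), ref=row["ref"], alt=row["alt"]
        )


def make_world(seed: int, config: WorldConfig | None = None) -> SyntheticWorld:
    """Build a fully specified synthetic world from a seed."""
    config = config or WorldConfig()
    rng = np.random.default_rng(seed)
    genome, transcripts = toy_gene_models(rng, config)
    gene_names = [t.gene_id for t in transcripts]

    space, measures, space_truth = simulate_disease_space(
        n_diseases=config.n_diseases,
        n_genes=config.n_genes,
        slope=config.slope,
        noise_sd=config.noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
        gene_names=gene_names,
        n_causal_genes=config.n_causal_genes,
        n_neutral_genes=config.n_neutral_genes,
        genes_per_disease=config.genes_per_disease,
        embedding_dim=config.embedding_dim,
        embedding_scale=config.embedding_scale,
        n_measures=config.n_measures,
        measure_noise_sd=config.measure_noise_sd,
        intercept=config.intercept,
        noise_corr=config.noise_corr,
    )
    causal_genes = set(space_truth["causal_genes"])
    tx_by_gene = {t.gene_id: t for t in transcripts}

    # ---- sample variant positions per region ----------------------------
    pools: dict[Region, list[tuple[str, int]]] = {r: [] for r in SPIKE_REGIONS}
    for t in transcripts:
        for region, positions in _region_positions(t, 500).items():
            pools[region] += [(t.gene_id, p) for p in positions]

    meta_rows = []

    def _sample(region: Region, count: int, causal: bool) -> int:
        pool = pools[region]
        if causal:
            eligible = [i for i, (g, _) in enumerate(pool) if g in causal_genes]
        else:
            eligible = list(range(len(pool)))
        rng.shuffle(eligible)
        taken = 0
        for i in eligible:
            if taken >= count:
                break
            gene_id, pos0 = pool[i]
            picked = _pick_alt(rng, genome, tx_by_gene[gene_id], pos0, region)
            if picked is None:
                continue
            ref, alt = picked
            meta_rows.append(
                {
                    "key": f"{tx_by_gene[gene_id].chrom}:{pos0 + 1}:{ref}:{alt}",
                    "chrom": tx_by_gene[gene_id].chrom,
                    "pos": pos0 + 1,
                    "ref": ref,
                    "alt": alt,
                    "region": region.value,
                    "gene_id": gene_id,
                    "causal": causal,
                }
            )
            taken += 1
        return taken

    for region in SPIKE_REGIONS:
        n_pool = config.n_pool[region.value]
        got_causal = _sample(region, config.n_causal_per_region, causal=True)
        if got_causal < config.n_causal_per_region:
            raise GlintsError(
                f"could only place {got_causal} causal variants in {region.value}"
            )
        used = {
            (r["gene_id"], r["pos"]) for r in meta_rows if r["region"] == region.value
        }
        pools[region] = [gp for gp in pools[region] if (gp[0], gp[1] + 1) not in used]
        got = _sample(region, n_pool, causal=False)
        if got < n_pool:
            raise GlintsError(
                f"could only place {got} neutral variants in {region.value}"
            )

    meta = pd.DataFrame(meta_rows).drop_duplicates(subset="key").set_index("key")

    # ---- draw the correlated score table --------------------------------
    registry = default_score_registry()
    source_names = list(registry)
    k = len(source_names)
    if config.score_corr is None:
        corr = default_score_correlation(source_names)
    else:
        corr = equicorrelation(k, config.score_corr)
    shift = np.full(k, config.causal_shift)
    n_rows = len(meta)
    causal_mask = meta["causal"].to_numpy()
    oriented = _draw_oriented(rng, n_rows, 0, corr, shift)
    oriented[causal_mask] += shift
    raw = _to_raw(oriented, source_names, registry)
    scores = pd.DataFrame(raw, index=meta.index, columns=source_names)
    # protein scores exist only for coding variants
    exon_rows = (meta["region"] == Region.EXON.value).to_numpy()
    for name, definition in registry.items():
        if Region.PROMOTER not in definition.applicable_regions:
            scores.loc[~exon_rows, name] = np.nan
        rate = (
            config.missing_rate_protein
            if Region.PROMOTER not in definition.applicable_regions
            else config.missing_rate_genome
        )
        if rate:
            drop = rng.random(n_rows) < rate
            scores.loc[drop, name] = np.nan

    truth = dict(space_truth)
    truth["causal_variant_keys"] = {
        r.value: list(meta.index[causal_mask & (meta["region"] == r.value)])
        for r in SPIKE_REGIONS
    }
    return SyntheticWorld(
        seed=seed,
        config=config,
        genome=genome,
        transcripts=transcripts,
        score_table=scores,
        variant_meta=meta,
        space=space,
        measures=measures,
        neutral_genes=list(space_truth["neutral_genes"]),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Candidate sets
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    """One spike-in draw: neutral controls plus a single causal variant."""

    variants: list[GenomicVariant]
    causal_key: str
    region: Region
    vcf_path: Path | None = None
    truth_path: Path | None = None


def simulate_candidates(
    world: SyntheticWorld,
    region: Region,
    n_neutral: int,
    seed: int = 0,
    *,
    causal_key: str | None = None,
    out_dir: str | Path | None = None,
) -> CandidateSet:
    """Sample ``n_neutral`` control SNVs of a region plus one spiked causal."""
    region = Region(region)
    causal_pool = world.causal_keys(region)
    if not causal_pool:
        raise GlintsError(f"world has no causal variants in region {region.value}")
    neutral_pool = world.neutral_keys(region)
    if len(neutral_pool) < n_neutral:
        raise GlintsError(
            f"region {region.value} has only {len(neutral_pool)} neutral variants"
        )
    rng = np.random.default_rng(seed)
    if causal_key is None:
        causal_key = str(rng.choice(causal_pool))
    elif causal_key not in causal_pool:
        raise GlintsError(f"{causal_key} is not a causal {region.value} variant")
    chosen = list(rng.choice(neutral_pool, size=n_neutral, replace=False))
    keys = chosen + [causal_key]
    variants = sorted(
        (world.variant(k) for k in keys), key=lambda v: (v.chrom, v.pos, v.ref, v.alt)
    )
    vcf_path = truth_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        vcf_path = out_dir / f"candidates_{region.value.lower()}.vcf"
        write_vcf(vcf_path, variants, contigs={c: len(s) for c, s in world.genome.items()})
        truth_path = out_dir / f"candidates_{region.value.lower()}.truth.json"
        with open(truth_path, "w") as fh:
            json.dump(
                {"causal_key": causal_key, "region": region.value, "n_neutral": n_neutral},
                fh, indent=2,
            )
    return CandidateSet(
        variants=variants, causal_key=causal_key, region=region,
        vcf_path=vcf_path, truth_path=truth_path,
    )


def write_vcf(
    path: str | Path,
    variants: Sequence[GenomicVariant],
    contigs: Mapping[str, int] | None = None,
) -> Path:
    """Write SNVs as a minimal uncompressed VCF 4.2 file."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}\t.\t.\t.\n"
            )
    return path
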