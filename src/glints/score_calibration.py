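"""Orientation and empirical calibration of functional scores.

Heterogeneous deleteriousness predictions cannot be combined directly: every
score is first *oriented* so that larger always means more deleterious
(SIFT and LRT, where smaller is worse, become 1-score), then converted to an
empirical p-value against a null panel built from a large background score
database with known causal variants excluded.

The empirical p-value uses the smoothed rank convention

    p = (r + 1) / (n + 1),   r = #{null >= oriented score},

which converges to the raw proportion of more extreme null scores for large
panels but can never be exactly zero -- a requirement of the downstream
-2 log p transform. Gene-level analytical p-values are calibrated the same
way against analytical p-values of neutral genes, with "more extreme"
meaning *smaller*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InsufficientNullError
from .variant_annotation import Region

ALL_REGIONS = frozenset(
    {Region.EXON, Region.PROMOTER, Region.INTRON, Region.SPLICE_SITE}
)
EXON_ONLY = frozenset({Region.EXON})


class Direction(str, Enum):
    HIGHER_WORSE = "higher_worse"
    LOWER_WORSE = "lower_worse"


@dataclass(frozen=True)
class ScoreDefinition:
    """Declared orientation and region applicability of one score source.

    ``unit_interval`` marks LOWER_WORSE scores on a [0,1] scale, which are
    oriented as ``1 - x``; other LOWER_WORSE scores are negated.
    """

    name: str
    direction: Direction
    applicable_regions: frozenset = ALL_REGIONS
    unit_interval: bool = False


#: The eight whole-genome scores (all four regions) and six protein scores
#: (coding region only) consumed by the default pipeline configuration.
WHOLE_GENOME_SCORES = (
    "CADD", "DANN", "FATHMM-MKL", "Eigen", "GERP", "phastCons", "SiPhy", "PhyloP",
)
PROTEIN_SCORES = (
    "MutationAssessor", "SIFT", "LRT", "MSRV", "PolyPhen2", "SinBaD",
)


def default_score_registry() -> dict[str, ScoreDefinition]:
    registry: dict[str, ScoreDefinition] = {}
    for name in WHOLE_GENOME_SCORES:
        registry[name] = ScoreDefinition(name, Direction.HIGHER_WORSE, ALL_REGIONS)
    for name in PROTEIN_SCORES:
        if name in ("SIFT", "LRT"):
            registry[name] = ScoreDefinition(
                name, Direction.LOWER_WORSE, EXON_ONLY, unit_interval=True
            )
        else:
            registry[name] = ScoreDefinition(name, Direction.HIGHER_WORSE, EXON_ONLY)
    return registry


def get_score_definition(
    name: str, registry: Mapping[str, ScoreDefinition]
) -> ScoreDefinition:
    try:
        return registry[name]
    except KeyError:
        raise ConfigurationError(
            f"score {name!r} is not configured; known scores: {sorted(registry)}"
        ) from None


def orient_score(definition: ScoreDefinition, raw):
    """Orient ``raw`` so that higher always means more deleterious.

    Accepts scalars or arrays; NaN (missing) passes through unchanged.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(np.isinf(raw)):
        raise ValueError(f"non-finite raw score for {definition.name}")
    if definition.direction is Direction.HIGHER_WORSE:
        oriented = raw
    elif definition.unit_interval:
        oriented = 1.0 - raw
    else:
        oriented = -raw
    return float(oriented) if oriented.ndim == 0 else oriented


def orient_table(
    scores: pd.DataFrame, registry: Mapping[str, ScoreDefinition]
) -> pd.DataFrame:
    """Orient every column of a per-variant score table."""
    out = {}
    for col in scores.columns:
        definition = get_score_definition(col, registry)
        out[col] = orient_score(definition, scores[col].to_numpy(dtype=float))
    return pd.DataFrame(out, index=scores.index)


# ---------------------------------------------------------------------------
# Empirical nulls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NullScoreDistribution:
    """Sorted null panel of oriented scores for one source."""

    score_name: str
    values: np.ndarray
    n: int = field(default=0)

    def __post_init__(self) -> None:
        values = np.sort(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "n", int(values.size))


def build_empirical_null(
    values,
    exclude: Iterable[str] = (),
    *,
    score_name: str = "",
    min_n: int = 100,
) -> NullScoreDistribution:
    """Build a null panel, excluding known-causal variant keys and NaNs.

    ``values`` may be a pandas Series (keys taken from the index) or a plain
    array (then ``exclude`` must be empty).
    """
    exclude = frozenset(exclude)
    if isinstance(values, pd.Series):
        if exclude:
            values = values[~values.index.isin(exclude)]
        arr = values.to_numpy(dtype=float)
    else:
        if exclude:
            raise ValueError("exclusion by key requires a keyed (Series) input")
        arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < min_n:
        raise InsufficientNullError(
            f"null panel for {score_name or 'score'} has {arr.size} values "
            f"(< {min_n}) after exclusion"
        )
    return NullScoreDistribution(score_name=score_name, values=arr)


def empirical_p_value(null: NullScoreDistribution, s):
    """Smoothed empirical p of oriented score(s) ``s``: (r+1)/(n+1), r = #{null >= s}."""
    s = np.asarray(s, dtype=float)
    # values sorted ascending; count >= s, ties inclusive (conservative).
    r = null.n - np.searchsorted(null.values, s, side="left")
    p = (r + 1.0) / (null.n + 1.0)
    p = np.where(np.isfinite(s), p, np.nan)
    return float(p) if p.ndim == 0 else p


def calibrate_gene_p(null_analytical, p_analytical):
    """Empirical p of analytical p-value(s) against a neutral-gene null.

    "More extreme" means *smaller* analytical p: p = (r+1)/(n+1) with
    r = #{null <= p_analytical}, ties inclusive.
    """
    null_sorted = np.sort(np.asarray(null_analytical, dtype=float))
    null_sorted = null_sorted[np.isfinite(null_sorted)]
    if null_sorted.size == 0:
        raise InsufficientNullError("empty neutral-gene null panel")
    q = np.asarray(p_analytical, dtype=float)
    r = np.searchsorted(null_sorted, q, side="right")
    p = (r + 1.0) / (null_sorted.size + 1.0)
    p = np.where(np.isfinite(q), p, np.nan)
    return float(p) if p.ndim == 0 else p


# ---------------------------------------------------------------------------
# Score panels
# ---------------------------------------------------------------------------

@dataclass
class ScorePanel:
    """Oriented scores and their empirical p-values for a candidate set.

    Both frames are indexed by variant key with one column per score source;
    NaN marks a missing (or region-inapplicable) source.
    """

    scores: pd.DataFrame
    pvalues: pd.DataFrame

    @property
    def mask(self) -> pd.DataFrame:
        return self.pvalues.notna()


def build_score_panel(
    raw_scores: pd.DataFrame,
    regions: pd.Series,
    nulls: Mapping[str, NullScoreDistribution],
    registry: Mapping[str, ScoreDefinition],
) -> ScorePanel:
    """Orient candidate scores, blank out region-inapplicable sources, and
    convert the rest to empirical p-values.

    ``regions`` maps variant key -> :class:`Region`; keys absent from
    ``raw_scores`` yield all-missing rows.
    """
    oriented = orient_table(raw_scores.reindex(regions.index), registry)
    region_values = regions.map(lambda r: Region(r))
    pvals = {}
    for col in oriented.columns:
        definition = get_score_definition(col, registry)
        applicable = region_values.map(
            lambda r: r in definition.applicable_regions
        ).to_numpy()
        vals = oriented[col].to_numpy(dtype=float)
        vals = np.where(applicable, vals, np.nan)
        oriented[col] = vals
        p = np.full(vals.shape, np.nan)
        present = np.isfinite(vals)
        if present.any():
            p[present] = empirical_p_value(nulls[col], vals[present])
        pvals[col] = p
    return ScorePanel(
        scores=oriented, pvalues=pd.DataFrame(pvals, index=oriented.index)
    )


# ---------------------------------------------------------------------------
# Null-panel persistence (one float per line + JSON sidecar)
# ---------------------------------------------------------------------------

def save_null_panel(null: NullScoreDistribution, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = null.score_name.replace("/", "_") or "score"
    data_path = directory / f"{stem}.null.txt"
    with open(data_path, "w") as fh:
        for v in null.values:
            fh.write(f"{float(v)!r}\n")
    with open(directory / f"{stem}.null.json", "w") as fh:
        json.dump({"score_name": null.score_name, "n": null.n}, fh)
    return data_path


def load_null_panel(directory: str | Path, score_name: str) -> NullScoreDistribution:
    directory = Path(directory)
    stem = score_name.replace("/", "_")
    with open(directory / f"{stem}.null.json") as fh:
        meta = json.load(fh)
    values = np.loadtxt(directory / f"{stem}.null.txt", dtype=float, ndmin=1)
    if values.size != meta["n"]:
        raise InsufficientNullError(
            f"null panel for {score_name} is truncated "
            f"({values.size} values, sidecar says {meta['n']})"
        )
    return NullScoreDistribution(score_name=meta["score_name"], values=values)
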