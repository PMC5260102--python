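"""Readers and writers for the package's tab-delimited resource layout.

A "space directory" (as written by ``glints simulate``) contains:

* ``genome.fa`` -- reference sequence (FASTA);
* ``genes.bed`` -- transcript models (BED12);
* ``scores.tsv`` -- background score database: ``chrom pos ref alt`` plus
  one column per score, ``.`` for missing;
* ``phenotype_<name>.tsv`` -- one disease x disease similarity matrix per
  phenotype vocabulary;
* ``gene_sim_<name>.tsv`` -- one gene x gene similarity matrix per measure;
* ``disease_genes.tsv`` -- two columns, disease and associated gene;
* ``neutral_genes.txt`` -- genes never reported disease-associated (used
  for gene-level calibration);
* ``causal_keys.txt`` -- variant keys excluded from score null panels;
* ``config.yaml`` / ``truth.json`` -- run metadata and simulation truth.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .association_regression import DiseaseSpace, GeneSimilarityMeasure
from .exceptions import FormatError
from .variant_annotation import TranscriptModel

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read a per-variant score TSV into a key-indexed frame of floats."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["."])
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"score table lacks required columns {missing}")
    keys = (
        df["chrom"].astype(str)
        + ":" + df["pos"].astype(int).astype(str)
        + ":" + df["ref"] + ":" + df["alt"]
    )
    out = df.drop(columns=VARIANT_COLUMNS).astype(float)
    out.index = keys
    return out


def write_score_table(scores: pd.DataFrame, path: str | Path) -> Path:
    """Write a key-indexed score frame as ``chrom pos ref alt score...`` TSV."""
    parts = scores.index.to_series().str.split(":", expand=True)
    meta = pd.DataFrame(
        {
            "chrom": parts[0].to_numpy(),
            "pos": parts[1].astype(int).to_numpy(),
            "ref": parts[2].to_numpy(),
            "alt": parts[3].to_numpy(),
        },
        index=scores.index,
    )
    full = pd.concat([meta, scores], axis=1)
    full.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.6g")
    return Path(path)


# ---------------------------------------------------------------------------
# Matrices and maps
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(mat: pd.DataFrame, path: str | Path) -> Path:
    mat.to_csv(path, sep="\t", float_format="%.8g")
    return Path(path)


def read_disease_genes(path: str | Path) -> dict[str, frozenset[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"disease", "gene"} <= set(df.columns):
        raise FormatError("disease-gene table needs 'disease' and 'gene' columns")
    out: dict[str, set[str]] = {}
    for disease, gene in zip(df["disease"], df["gene"]):
        out.setdefault(disease, set()).add(gene)
    return {d: frozenset(g) for d, g in out.items()}


def write_disease_genes(mapping: Mapping[str, frozenset[str]], path: str | Path) -> Path:
    rows = [
        {"disease": d, "gene": g}
        for d in sorted(mapping)
        for g in sorted(mapping[d])
    ]
    pd.DataFrame(rows, columns=["disease", "gene"]).to_csv(path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# FASTA / BED12
# ---------------------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> Path:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")
    return Path(path)


def write_bed12(transcripts: Sequence[TranscriptModel], path: str | Path) -> Path:
    with open(path, "w") as fh:
        for t in transcripts:
            sizes = ",".join(str(e - s) for s, e in t.exons)
            starts = ",".join(str(s - t.start) for s, _ in t.exons)
            fh.write(
                "\t".join(
                    [
                        t.chrom, str(t.start), str(t.end), t.gene_id, "0",
                        t.strand, str(t.cds_start), str(t.cds_end), "0",
                        str(len(t.exons)), sizes, starts,
                    ]
                )
                + "\n"
            )
    return Path(path)


# ---------------------------------------------------------------------------
# Space directories
# ---------------------------------------------------------------------------

def write_space_dir(world, out_dir: str | Path) -> Path:
    """Persist a synthetic world as a self-contained space directory."""
    from dataclasses import asdict

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(world.genome, out / "genome.fa")
    write_bed12(world.transcripts, out / "genes.bed")
    write_score_table(world.score_table, out / "scores.tsv")
    for name, mat in world.space.phenotype_sims.items():
        write_matrix(mat, out / f"phenotype_{name}.tsv")
    for name, measure in world.measures.items():
        write_matrix(measure.phi, out / f"gene_sim_{name}.tsv")
    write_disease_genes(world.space.disease_genes, out / "disease_genes.tsv")
    (out / "neutral_genes.txt").write_text(
        "\n".join(world.neutral_genes) + "\n"
    )
    (out / "causal_keys.txt").write_text(
        "\n".join(sorted(world.known_causal_keys)) + "\n"
    )
    with open(out / "truth.json", "w") as fh:
        json.dump(world.truth, fh, indent=2)
    config = asdict(world.config)
    config["n_pool"] = dict(config["n_pool"])
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "seed": world.seed,
                "query_disease": world.truth["query_disease"],
                "diseases": world.space.diseases,
                "world_config": config,
            },
            fh,
        )
    return out


def load_space_dir(space_dir: str | Path):
    """Load a space directory into a :class:`~glints.pipeline.PipelineResources`."""
    from pyfaidx import Fasta

    from .pipeline import PipelineResources
    from .variant_annotation import load_gene_models

    space_dir = Path(space_dir)
    phenotype_sims = {
        p.stem.removeprefix("phenotype_"): read_matrix(p)
        for p in sorted(space_dir.glob("phenotype_*.tsv"))
    }
    measures = {
        p.stem.removeprefix("gene_sim_"): GeneSimilarityMeasure(
            name=p.stem.removeprefix("gene_sim_"), phi=read_matrix(p)
        )
        for p in sorted(space_dir.glob("gene_sim_*.tsv"))
    }
    disease_genes = read_disease_genes(space_dir / "disease_genes.tsv")
    diseases = sorted(
        set(next(iter(phenotype_sims.values())).index.astype(str))
    )
    space = DiseaseSpace(
        diseases=diseases,
        phenotype_sims=phenotype_sims,
        disease_genes=disease_genes,
    )
    neutral_path = space_dir / "neutral_genes.txt"
    neutral_genes = (
        neutral_path.read_text().split() if neutral_path.exists() else []
    )
    causal_path = space_dir / "causal_keys.txt"
    causal_keys = (
        frozenset(causal_path.read_text().split()) if causal_path.exists() else frozenset()
    )
    return PipelineResources(
        transcripts=load_gene_models(space_dir / "genes.bed"),
        genome=Fasta(str(space_dir / "genome.fa")),
        score_table=read_score_table(space_dir / "scores.tsv"),
        space=space,
        measures=measures,
        neutral_genes=neutral_genes,
        known_causal_keys=causal_keys,
    )
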