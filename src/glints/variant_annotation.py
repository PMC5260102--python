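"""Region classification of single-nucleotide variants against gene models.

Candidate SNVs are assigned to one of four region classes relative to a set of
transcript models, or discarded:

* ``EXON`` -- a nonsynonymous substitution inside the coding sequence;
* ``SPLICE_SITE`` -- the two innermost intronic bases at an exon/intron
  boundary (the canonical splice dinucleotides, intron offsets 1-2);
* ``INTRON`` -- near-boundary intronic bases at offsets 3-10;
* ``PROMOTER`` -- the strand-aware window 500 bp upstream of the transcription
  start site, plus the 5' and 3' untranslated regions.

Everything else (intergenic, deep-intronic, synonymous coding) is discarded.
Internal coordinates are 0-based half-open; VCF positions (1-based) are
converted on read. When a variant hits several transcripts or classes, the
most severe class wins: EXON > SPLICE_SITE > INTRON > PROMOTER.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from pathlib import Path
from typing import Iterable

from Bio.Seq import Seq

from .exceptions import (
    DataIntegrityError,
    FormatError,
    GlintsError,
    ValidationError,
)

logger = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Default promoter window length (bases upstream of the TSS).
DEFAULT_PROMOTER_WINDOW = 500
#: Intron offsets (inclusive, counted from the intron side) for splice sites.
SPLICE_OFFSETS = (1, 2)
#: Intron offsets (inclusive) for the near-boundary intronic class.
INTRON_OFFSETS = (3, 10)


class Region(str, Enum):
    """Region class of a candidate SNV."""

    EXON = "Exon"
    PROMOTER = "Promoter"
    INTRON = "Intron"
    SPLICE_SITE = "Splice_site"
    DISCARD = "Discard"


#: Severity order used when a variant hits several transcripts/classes.
REGION_PRECEDENCE = {
    Region.EXON: 0,
    Region.SPLICE_SITE: 1,
    Region.INTRON: 2,
    Region.PROMOTER: 3,
    Region.DISCARD: 4,
}


@dataclass(frozen=True)
class GenomicVariant:
    """One single-nucleotide variant, with a 1-based VCF-style position."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.pos}")
        if self.ref not in _NUCLEOTIDES or self.alt not in _NUCLEOTIDES:
            raise ValidationError(
                f"ref/alt must be single nucleotides in ACGT, got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt are identical ({self.ref})")

    @property
    def pos0(self) -> int:
        """0-based genomic position."""
        return self.pos - 1

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(eq=False)
class TranscriptModel:
    """A transcript as an ordered set of exons with CDS bounds.

    ``exons`` are 0-based half-open intervals, sorted and non-overlapping.
    ``cds_start``/``cds_end`` delimit the coding sequence in genomic
    coordinates (cds_start == cds_end for a noncoding transcript).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"strand must be '+' or '-', got {self.strand!r} ({self.gene_id})"
            )
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not self.exons:
            raise ValidationError(f"transcript {self.gene_id} has no exons")
        for s, e in self.exons:
            if e <= s:
                raise ValidationError(f"empty exon [{s},{e}) in {self.gene_id}")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"exons of {self.gene_id} overlap or are unsorted"
                )
        if not (self.start <= self.cds_start <= self.cds_end <= self.end):
            raise ValidationError(
                f"CDS bounds [{self.cds_start},{self.cds_end}) of {self.gene_id} "
                f"fall outside the exon span"
            )

    # -- basic geometry ----------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start: leftmost coordinate on '+', rightmost on '-'.

        On the minus strand this is the half-open end coordinate, i.e. the
        boundary just right of the first transcribed base.
        """
        return self.start if self.strand == "+" else self.end

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    @cached_property
    def cds_intervals(self) -> tuple[tuple[int, int], ...]:
        """Exon pieces intersected with the CDS bounds (genomic order)."""
        out = []
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if ce > cs:
                out.append((cs, ce))
        return tuple(out)

    @cached_property
    def utr_intervals(self) -> dict[str, tuple[tuple[int, int], ...]]:
        """5'/3' UTR intervals, strand-aware."""
        left, right = [], []
        for s, e in self.exons:
            if s < self.cds_start:
                left.append((s, min(e, self.cds_start)))
            if e > self.cds_end:
                right.append((max(s, self.cds_end), e))
        if self.strand == "+":
            return {"utr5": tuple(left), "utr3": tuple(right)}
        return {"utr5": tuple(right), "utr3": tuple(left)}

    @cached_property
    def coding_positions(self) -> tuple[int, ...]:
        """Genomic positions of coding bases in translation order."""
        pos = [p for s, e in self.cds_intervals for p in range(s, e)]
        if self.strand == "-":
            pos.reverse()
        return tuple(pos)

    @cached_property
    def _coding_index(self) -> dict[int, int]:
        return {p: i for i, p in enumerate(self.coding_positions)}


@dataclass(frozen=True)
class RegionAssignment:
    """Result of classifying one variant against the gene models."""

    region: Region
    gene_id: str
    detail: str = ""

    def __post_init__(self) -> None:
        if (self.region is Region.DISCARD) != (self.gene_id == ""):
            raise ValidationError("DISCARD assignments must have an empty gene_id")


# ---------------------------------------------------------------------------
# Reference-genome access
# ---------------------------------------------------------------------------

def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch ``genome[chrom][start:end]`` (0-based half-open), uppercased.

    Accepts pysam.FastaFile-style objects (``fetch``), pyfaidx.Fasta, plain
    ``dict[str, str]`` mappings, or anything else whose items slice to a
    string-convertible object.
    """
    if hasattr(genome, "fetch"):
        return str(genome.fetch(chrom, start, end)).upper()
    try:
        record = genome[chrom]
    except KeyError as exc:
        raise GlintsError(f"chromosome {chrom!r} not found in genome") from exc
    piece = record[start:end]
    if hasattr(piece, "seq"):  # pyfaidx.Sequence / Bio.SeqRecord slices
        piece = piece.seq
    return str(piece).upper()


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Gene-model loading
# ---------------------------------------------------------------------------

def load_gene_models(path: str | Path, dialect: str | None = None) -> list[TranscriptModel]:
    """Load transcript models from a BED12 or minimal GFF3 file.

    The dialect is sniffed from the file extension unless given explicitly
    (``"bed12"`` or ``"gff3"``).
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        if suffix in (".bed", ".bed12"):
            dialect = "bed12"
        elif suffix in (".gff", ".gff3", ".gtf"):
            dialect = "gff3"
        else:
            raise FormatError(f"cannot infer gene-model dialect from {path.name!r}")
    if dialect == "bed12":
        return _load_bed12(path)
    if dialect == "gff3":
        return _load_gff3(path)
    raise FormatError(f"unknown gene-model dialect {dialect!r}")


def _load_bed12(path: Path) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path.name} line {lineno}: expected 12 BED fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                chrom_start = int(fields[1])
                name = fields[3]
                strand = fields[5]
                thick_start, thick_end = int(fields[6]), int(fields[7])
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path.name} line {lineno}: {exc}") from exc
            if len(sizes) != block_count or len(starts) != block_count:
                raise FormatError(
                    f"{path.name} line {lineno}: block count does not match block lists"
                )
            exons = tuple(
                (chrom_start + off, chrom_start + off + size)
                for off, size in zip(starts, sizes)
            )
            models.append(
                TranscriptModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds_start=thick_start,
                    cds_end=thick_end,
                    transcript_id=name,
                )
            )
    return models


def _load_gff3(path: Path) -> list[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for ftype in ("mRNA", "transcript"):
        for tx in db.features_of_type(ftype):
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(tx, featuretype="exon")
            )
            cds = sorted(
                (f.start - 1, f.end) for f in db.children(tx, featuretype="CDS")
            )
            if not exons:
                exons = [(tx.start - 1, tx.end)]
            cds_start = min(s for s, _ in cds) if cds else exons[0][0]
            cds_end = max(e for _, e in cds) if cds else exons[0][0]
            gene_id = tx.attributes.get("gene_id", tx.attributes.get("Parent", [tx.id]))[0]
            models.append(
                TranscriptModel(
                    gene_id=gene_id,
                    chrom=tx.seqid,
                    strand=tx.strand,
                    exons=tuple(exons),
                    cds_start=cds_start,
                    cds_end=cds_end,
                    transcript_id=tx.id,
                )
            )
    return models


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def is_nonsynonymous(
    v: GenomicVariant,
    t: TranscriptModel,
    genome,
    *,
    count_stop_changes: bool = True,
) -> tuple[bool, str]:
    """Decide whether ``v`` changes the encoded amino acid of ``t``.

    Returns ``(changed, detail)`` with detail like ``"M12I"``. The variant
    must fall inside the transcript's CDS. Raises
    :class:`DataIntegrityError` if the genome base at the variant position
    does not match ``v.ref``. A CDS whose length is not a multiple of three
    triggers a warning; the variant is then judged on its local codon only,
    and a trailing incomplete codon is reported as not amino-acid-changing.
    """
    idx = t._coding_index.get(v.pos0)
    if idx is None:
        raise GlintsError(
            f"variant {v.key} is not inside the CDS of {t.gene_id}"
        )
    if len(t.coding_positions) % 3 != 0:
        warnings.warn(
            f"CDS length of {t.gene_id} is not a multiple of 3; "
            "classifying via the local codon only",
            stacklevel=2,
        )
    genome_ref = fetch_sequence(genome, v.chrom, v.pos0, v.pos0 + 1)
    if genome_ref != v.ref:
        raise DataIntegrityError(
            f"reference mismatch at {v.chrom}:{v.pos}: VCF says {v.ref}, "
            f"genome says {genome_ref}"
        )
    codon_i = idx // 3
    codon_positions = t.coding_positions[codon_i * 3 : codon_i * 3 + 3]
    if len(codon_positions) < 3:
        return False, "incomplete_codon"
    bases = []
    for p in codon_positions:
        b = fetch_sequence(genome, v.chrom, p, p + 1)
        bases.append(b if t.strand == "+" else b.translate(_COMPLEMENT))
    ref_codon = "".join(bases)
    alt_base = v.alt if t.strand == "+" else v.alt.translate(_COMPLEMENT)
    within = idx - codon_i * 3
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    detail = f"{aa_ref}{codon_i + 1}{aa_alt}"
    changed = aa_ref != aa_alt
    if changed and not count_stop_changes and "*" in (aa_ref + aa_alt):
        return False, detail
    return changed, detail


def _classify_in_transcript(
    v: GenomicVariant,
    t: TranscriptModel,
    genome,
    *,
    promoter_window: int,
    count_stop_changes: bool,
) -> tuple[Region, str] | None:
    if t.chrom != v.chrom:
        return None
    pos0 = v.pos0

    # Coding exon: only a nonsynonymous change qualifies.
    if pos0 in t._coding_index:
        if genome is None:
            raise GlintsError(
                "a reference genome is required to translate coding variants"
            )
        changed, detail = is_nonsynonymous(
            v, t, genome, count_stop_changes=count_stop_changes
        )
        return (Region.EXON, detail) if changed else None

    # UTR exon bases belong to the promoter class.
    for label, intervals in t.utr_intervals.items():
        for s, e in intervals:
            if s <= pos0 < e:
                return Region.PROMOTER, label

    # Intronic bases near a boundary: splice site (1-2) or intron (3-10).
    for s, e in t.introns:
        if s <= pos0 < e:
            offset = min(pos0 - s + 1, e - pos0)
            if SPLICE_OFFSETS[0] <= offset <= SPLICE_OFFSETS[1]:
                return Region.SPLICE_SITE, f"intron_offset={offset}"
            if INTRON_OFFSETS[0] <= offset <= INTRON_OFFSETS[1]:
                return Region.INTRON, f"intron_offset={offset}"
            return None

    # Strand-aware upstream promoter window.
    if t.strand == "+":
        if t.start - promoter_window <= pos0 < t.start:
            return Region.PROMOTER, f"upstream={t.start - pos0}"
    else:
        if t.end <= pos0 < t.end + promoter_window:
            return Region.PROMOTER, f"upstream={pos0 - t.end + 1}"
    return None


def classify_variant_all(
    v: GenomicVariant,
    transcripts: Iterable[TranscriptModel],
    genome=None,
    *,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
    count_stop_changes: bool = True,
) -> list[RegionAssignment]:
    """All non-discard assignments of ``v``, one (best) per host gene.

    Sorted by severity, then gene id -- the first element is the assignment
    :func:`classify_variant` returns.
    """
    per_gene: dict[str, tuple[Region, str]] = {}
    for t in transcripts:
        hit = _classify_in_transcript(
            v, t, genome,
            promoter_window=promoter_window,
            count_stop_changes=count_stop_changes,
        )
        if hit is None:
            continue
        region, detail = hit
        prev = per_gene.get(t.gene_id)
        if prev is None or REGION_PRECEDENCE[region] < REGION_PRECEDENCE[prev[0]]:
            per_gene[t.gene_id] = (region, detail)
    out = [
        RegionAssignment(region=r, gene_id=g, detail=d)
        for g, (r, d) in per_gene.items()
    ]
    out.sort(key=lambda a: (REGION_PRECEDENCE[a.region], a.gene_id, a.detail))
    return out


def classify_variant(
    v: GenomicVariant,
    transcripts: Iterable[TranscriptModel],
    genome=None,
    *,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
    count_stop_changes: bool = True,
) -> RegionAssignment:
    """Classify ``v`` into EXON/SPLICE_SITE/INTRON/PROMOTER or DISCARD."""
    hits = classify_variant_all(
        v, transcripts, genome,
        promoter_window=promoter_window,
        count_stop_changes=count_stop_changes,
    )
    if hits:
        return hits[0]
    return RegionAssignment(region=Region.DISCARD, gene_id="", detail="no_region")


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> tuple[list[GenomicVariant], int]:
    """Read SNV records from a VCF; multi-allelic records are split.

    Returns the variants plus the number of skipped non-SNV alleles.
    """
    from cyvcf2 import VCF

    variants: list[GenomicVariant] = []
    skipped = 0
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            if (
                len(rec.REF) == 1
                and len(alt) == 1
                and rec.REF in _NUCLEOTIDES
                and alt in _NUCLEOTIDES
            ):
                variants.append(
                    GenomicVariant(
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        id=rec.ID,
                    )
                )
            else:
                skipped += 1
    if skipped:
        logger.info("skipped %d non-SNV alleles while reading VCF", skipped)
    return variants, skipped
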