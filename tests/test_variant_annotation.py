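"""Region classification, gene-model parsing and codon translation."""

import numpy as np
import pytest

from glints.exceptions import DataIntegrityError, FormatError, ValidationError
from glints.io import write_bed12
from glints.synthetic_data import write_vcf
from glints.variant_annotation import (
    GenomicVariant,
    Region,
    TranscriptModel,
    classify_variant,
    classify_variant_all,
    is_nonsynonymous,
    load_gene_models,
    read_vcf,
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [
        dict(chrom="1", pos=0, ref="A", alt="C"),
        dict(chrom="1", pos=5, ref="A", alt="A"),
        dict(chrom="1", pos=5, ref="N", alt="A"),
        dict(chrom="1", pos=5, ref="AT", alt="A"),
    ],
)
def test_variant_invariants_rejected(kwargs):
    with pytest.raises(ValidationError):
        GenomicVariant(**kwargs)


def test_minus_strand_tss_is_right_boundary():
    t = TranscriptModel(
        gene_id="g", chrom="1", strand="-", exons=((1000, 2000),),
        cds_start=1000, cds_end=2000,
    )
    assert t.tss == 2000


def test_transcript_invariants_rejected():
    with pytest.raises(ValidationError):
        TranscriptModel(
            gene_id="g", chrom="1", strand=".", exons=((0, 10),),
            cds_start=0, cds_end=10,
        )
    with pytest.raises(ValidationError):
        TranscriptModel(  # overlapping exons
            gene_id="g", chrom="1", strand="+", exons=((0, 10), (5, 20)),
            cds_start=0, cds_end=20,
        )


# ---------------------------------------------------------------------------
# Gene-model loading
# ---------------------------------------------------------------------------

def test_bed12_two_blocks(tmp_path):
    line = "chr1\t100\t500\tGENE\t0\t+\t150\t450\t0\t2\t100,100\t0,300\n"
    path = tmp_path / "genes.bed"
    path.write_text(line)
    models = load_gene_models(path)
    assert len(models) == 1
    t = models[0]
    assert t.exons == ((100, 200), (400, 500))
    assert (t.cds_start, t.cds_end) == (150, 450)


def test_bed12_bad_strand_and_format(tmp_path):
    path = tmp_path / "genes.bed"
    path.write_text("chr1\t100\t500\tG\t0\t.\t150\t450\t0\t1\t400\t0\n")
    with pytest.raises(ValidationError):
        load_gene_models(path)
    path.write_text("chr1\t100\n")
    with pytest.raises(FormatError, match="line 1"):
        load_gene_models(path)


def test_bed12_roundtrip(tmp_path, small_world):
    path = write_bed12(small_world.transcripts, tmp_path / "genes.bed")
    loaded = load_gene_models(path)
    assert len(loaded) == len(small_world.transcripts)
    for a, b in zip(loaded, small_world.transcripts):
        assert (a.gene_id, a.strand, a.exons, a.cds_start, a.cds_end) == (
            b.gene_id, b.strand, b.exons, b.cds_start, b.cds_end,
        )


def test_gff3_minimal(tmp_path):
    gff = "\n".join(
        [
            "##gff-version 3",
            "chr1\tsrc\tgene\t101\t500\t.\t+\t.\tID=gene1",
            "chr1\tsrc\tmRNA\t101\t500\t.\t+\t.\tID=tx1;Parent=gene1",
            "chr1\tsrc\texon\t101\t200\t.\t+\t.\tID=e1;Parent=tx1",
            "chr1\tsrc\texon\t401\t500\t.\t+\t.\tID=e2;Parent=tx1",
            "chr1\tsrc\tCDS\t151\t200\t.\t+\t0\tID=c1;Parent=tx1",
            "chr1\tsrc\tCDS\t401\t450\t.\t+\t0\tID=c2;Parent=tx1",
        ]
    )
    path = tmp_path / "genes.gff3"
    path.write_text(gff + "\n")
    (t,) = load_gene_models(path)
    assert t.exons == ((100, 200), (400, 500))
    assert (t.cds_start, t.cds_end) == (150, 450)


# ---------------------------------------------------------------------------
# Classification on the toy locus
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pos0,expected,detail_part",
    [
        (1100, Region.SPLICE_SITE, "offset=1"),   # first intron base (donor +1)
        (1101, Region.SPLICE_SITE, "offset=2"),
        (1199, Region.SPLICE_SITE, "offset=1"),   # acceptor -1
        (1104, Region.INTRON, "offset=5"),
        (1109, Region.INTRON, "offset=10"),
        (1150, Region.DISCARD, ""),               # offset 50: deep intronic
        (600, Region.PROMOTER, "upstream=400"),   # 400 bp upstream of TSS
        (999, Region.PROMOTER, "upstream=1"),
        (400, Region.DISCARD, ""),                # 600 bp upstream: outside window
        (2000, Region.DISCARD, ""),               # downstream / intergenic
    ],
)
def test_noncoding_classification(toy_transcript, toy_genome, pos0, expected, detail_part):
    base = toy_genome["chrT"][pos0]
    alt = "A" if base != "A" else "C"
    v = GenomicVariant(chrom="chrT", pos=pos0 + 1, ref=base, alt=alt)
    result = classify_variant(v, [toy_transcript], toy_genome)
    assert result.region is expected
    assert detail_part in result.detail


def test_nonsynonymous_met_to_ile(toy_transcript, toy_genome):
    # codon 1 is ATG; G->A at its third base gives ATA (Met->Ile)
    v = GenomicVariant(chrom="chrT", pos=1003, ref="G", alt="A")
    changed, detail = is_nonsynonymous(v, toy_transcript, toy_genome)
    assert changed and detail == "M1I"
    assert classify_variant(v, [toy_transcript], toy_genome).region is Region.EXON


def test_synonymous_leu_to_leu(toy_transcript, toy_genome):
    # codon 2 is CTG; C->T at its first base gives TTG (Leu->Leu)
    v = GenomicVariant(chrom="chrT", pos=1004, ref="C", alt="T")
    changed, detail = is_nonsynonymous(v, toy_transcript, toy_genome)
    assert not changed and detail == "L2L"
    assert classify_variant(v, [toy_transcript], toy_genome).region is Region.DISCARD


def test_synonymous_never_exon_by_enumeration(toy_transcript, toy_genome):
    """All 9 substitutions of the first two codons: EXON iff the amino acid
    changes under the standard genetic code."""
    from Bio.Seq import Seq

    for pos0 in range(1000, 1006):
        ref = toy_genome["chrT"][pos0]
        codon_start = 1000 + ((pos0 - 1000) // 3) * 3
        ref_codon = toy_genome["chrT"][codon_start : codon_start + 3]
        for alt in "ACGT":
            if alt == ref:
                continue
            off = pos0 - codon_start
            alt_codon = ref_codon[:off] + alt + ref_codon[off + 1 :]
            expect_exon = str(Seq(ref_codon).translate()) != str(Seq(alt_codon).translate())
            v = GenomicVariant(chrom="chrT", pos=pos0 + 1, ref=ref, alt=alt)
            result = classify_variant(v, [toy_transcript], toy_genome)
            assert (result.region is Region.EXON) == expect_exon


def test_reference_mismatch_raises(toy_transcript, toy_genome):
    base = toy_genome["chrT"][1010]
    wrong = "A" if base != "A" else "C"
    other = next(b for b in "ACGT" if b not in (wrong, base))
    v = GenomicVariant(chrom="chrT", pos=1011, ref=wrong, alt=other)
    with pytest.raises(DataIntegrityError):
        is_nonsynonymous(v, toy_transcript, toy_genome)


def test_minus_strand_codon_evaluated_on_reverse_complement():
    # minus-strand CDS of one codon: genomic CAT -> transcript ATG (Met);
    # genomic C->T at the codon's genomic start is transcript G->A at the
    # third codon position: ATG->ATA (Met->Ile), nonsynonymous.
    genome = {"chrM": "A" * 100 + "CAT" + "A" * 100}
    t = TranscriptModel(
        gene_id="gm", chrom="chrM", strand="-", exons=((100, 103),),
        cds_start=100, cds_end=103,
    )
    v = GenomicVariant(chrom="chrM", pos=101, ref="C", alt="T")
    changed, detail = is_nonsynonymous(v, t, genome)
    assert changed and detail == "M1I"


def test_classification_is_strand_symmetric(toy_transcript, toy_genome):
    """Mirroring the locus and flipping strand yields identical labels."""
    comp = str.maketrans("ACGT", "TGCA")
    seq = toy_genome["chrT"]
    L = len(seq)
    mirrored_genome = {"chrT": seq.translate(comp)[::-1]}
    mirrored = TranscriptModel(
        gene_id="TOY1", chrom="chrT", strand="-",
        exons=tuple(sorted((L - e, L - s) for s, e in toy_transcript.exons)),
        cds_start=L - toy_transcript.cds_end,
        cds_end=L - toy_transcript.cds_start,
    )
    rng = np.random.default_rng(5)
    positions = list(rng.integers(380, 2100, size=60))
    for pos0 in positions:
        ref = seq[pos0]
        alt = next(b for b in "ACGT" if b != ref)
        v = GenomicVariant(chrom="chrT", pos=pos0 + 1, ref=ref, alt=alt)
        m_pos0 = L - 1 - pos0
        mv = GenomicVariant(
            chrom="chrT", pos=m_pos0 + 1,
            ref=ref.translate(comp), alt=alt.translate(comp),
        )
        a = classify_variant(v, [toy_transcript], toy_genome)
        b = classify_variant(mv, [mirrored], mirrored_genome)
        assert a.region is b.region, f"pos {pos0}: {a.region} != {b.region}"


def test_precedence_exon_over_promoter(toy_genome, toy_transcript):
    """A variant in gene A's coding exon and gene B's promoter window gets
    EXON overall, and both genes appear in the full assignment list."""
    other = TranscriptModel(
        gene_id="TOY2", chrom="chrT", strand="-",
        exons=((100, 400),), cds_start=100, cds_end=400,
    )
    # pos0 1002 is coding (ATG codon) for TOY1 and 603 bp beyond TOY2's
    # window; use pos0 699 for promoter-only, pos0 1002 for exon+nothing.
    v = GenomicVariant(chrom="chrT", pos=1003, ref="G", alt="A")
    hits = classify_variant_all(v, [toy_transcript, other], toy_genome, promoter_window=700)
    assert [h.region for h in hits] == [Region.EXON, Region.PROMOTER]
    assert classify_variant(v, [toy_transcript, other], toy_genome,
                            promoter_window=700).region is Region.EXON


def test_stop_gain_toggle(toy_genome):
    # TAC -> TAA is Tyr -> stop
    genome = {"chrS": "A" * 99 + "TAC" + "G" * 100}
    t = TranscriptModel(
        gene_id="gs", chrom="chrS", strand="+", exons=((99, 102),),
        cds_start=99, cds_end=102,
    )
    v = GenomicVariant(chrom="chrS", pos=102, ref="C", alt="A")
    assert is_nonsynonymous(v, t, genome)[0]
    assert not is_nonsynonymous(v, t, genome, count_stop_changes=False)[0]


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def test_read_vcf_splits_multiallelic_and_skips_indels(tmp_path):
    path = tmp_path / "cand.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=1000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t10\t.\tA\tG,T\t.\t.\t.\n"
        "chr1\t20\t.\tA\tAT\t.\t.\t.\n"
        "chr1\t30\trs1\tC\tG\t.\t.\t.\n"
    )
    variants, skipped = read_vcf(path)
    assert [v.key for v in variants] == ["chr1:10:A:G", "chr1:10:A:T", "chr1:30:C:G"]
    assert skipped == 1
    assert variants[2].id == "rs1"


def test_write_vcf_roundtrip(tmp_path):
    variants = [
        GenomicVariant(chrom="chr1", pos=5, ref="A", alt="T"),
        GenomicVariant(chrom="chr1", pos=9, ref="G", alt="C"),
    ]
    path = write_vcf(tmp_path / "x.vcf", variants, contigs={"chr1": 100})
    back, skipped = read_vcf(path)
    assert skipped == 0
    assert [v.key for v in back] == [v.key for v in variants]
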