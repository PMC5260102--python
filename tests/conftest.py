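"""Shared fixtures: a hand-drawn toy locus and a small synthetic world."""

from __future__ import annotations

import numpy as np
import pytest

from glints.synthetic_data import SMALL_CONFIG, make_world
from glints.variant_annotation import TranscriptModel


def _toy_genome(length: int = 2600, seed: int = 42) -> dict[str, str]:
    rng = np.random.default_rng(seed)
    seq = list("ACGT"[i] for i in rng.integers(0, 4, size=length))
    # plant known codons at the CDS start of the toy transcript (pos 1000):
    # ATG (Met), CTG (Leu), then arbitrary bases
    seq[1000:1006] = list("ATGCTG")
    return {"chrT": "".join(seq)}


@pytest.fixture(scope="session")
def toy_genome() -> dict[str, str]:
    return _toy_genome()


@pytest.fixture(scope="session")
def toy_transcript() -> TranscriptModel:
    """Plus-strand transcript, exons [1000,1100) + [1200,1300), CDS = exon union."""
    return TranscriptModel(
        gene_id="TOY1",
        chrom="chrT",
        strand="+",
        exons=((1000, 1100), (1200, 1300)),
        cds_start=1000,
        cds_end=1300,
    )


@pytest.fixture(scope="session")
def small_world():
    """A small synthetic world shared by read-only tests."""
    return make_world(123, SMALL_CONFIG)
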