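"""Shared fixtures: a small functional multi-exon gene and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from gekkota.pseudogene import GeneModel
from gekkota.selection import SENSE_CODONS


def make_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random functional CDS: ATG + random non-stop/non-ATG codons + TAA."""
    sense = sorted(SENSE_CODONS - {"ATG"})
    body = "".join(sense[i] for i in rng.integers(0, len(sense), size=n_codons - 2))
    return "ATG" + body + "TAA"


@pytest.fixture
def functional_gene():
    """A 60-codon, 3-exon plus-strand gene embedded in a contig.

    Returns (model, contig, cds, exon_lengths).
    """
    rng = np.random.default_rng(42)
    cds = make_cds(60, rng)  # 180 bp
    exon_lengths = [60, 66, 54]
    intron = "GTAAGTGCATCGATCGTACG"
    contig = "TTTTT" + cds[:60] + intron + cds[60:126] + intron + cds[126:] + "GGGGG"
    model = GeneModel(
        id="RH1", exons=((5, 65), (85, 151), (171, 225)), strand="+",
        contig_id="ctg1",
    )
    return model, contig, cds, exon_lengths
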