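"""Shared fixtures: tiny deterministic genomes, transcripts and matrices."""

from __future__ import annotations

import numpy as np
import pytest

from isoswitch.genome import Exon, GenomeSequence, TranscriptModel


def make_tx(exons, tx_id="tx1", gene_id="g1", strand="+", chrom="chr1"):
    return TranscriptModel(
        tx_id, gene_id, strand, [Exon(chrom, s, e, strand) for s, e in exons]
    )


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def random_models(rng: np.random.Generator, n: int):
    """Random valid gene models (1-3 transcripts, 1-5 exons) on one genome."""
    from isoswitch.genome import GeneModel

    genes = []
    for i in range(n):
        gene_id = f"g{i:03d}"
        chrom = f"chr{i % 4}"
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        txs = []
        for j in range(int(rng.integers(1, 4))):
            pos = int(rng.integers(0, 50))
            exons = []
            for _ in range(int(rng.integers(1, 6))):
                length = int(rng.integers(5, 40))
                exons.append((pos, pos + length))
                pos += length + int(rng.integers(2, 30))
            txs.append(make_tx(exons, f"{gene_id}.t{j}", gene_id, strand, chrom))
        genes.append(GeneModel(gene_id, txs))
    return genes


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_genome(rng):
    return GenomeSequence({
        "chr1": random_sequence(rng, 5000),
        "chr2": random_sequence(rng, 5000),
    })
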