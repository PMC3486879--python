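"""Shared fixtures: tiny genomes written to disk, worked motif examples, and a
small simulated dataset reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from exonskip.io import GeneModel, MotifSet, SnpRecord, TranscriptModel, read_fasta, write_fasta
from exonskip.simulate import SimConfig, simulate_all


def make_genome(tmp_path, sequences: dict[str, str]):
    """Write sequences to FASTA and return a GenomeAccessor."""
    path = tmp_path / "genome.fa"
    write_fasta(sequences, path)
    return read_fasta(path)


def window_genome(tmp_path, window: str, chrom: str = "1", snp_pos: int = 50):
    """Embed an 11-mer window (SNP base at its center) in a padded chromosome.

    Returns (accessor, snp_pos).  Padding is poly-A so tests control exactly
    which hexamers can match.
    """
    assert len(window) % 2 == 1
    flank = len(window) // 2
    seq = "A" * (snp_pos - flank) + window + "A" * 40
    return make_genome(tmp_path, {chrom: seq}), snp_pos


@pytest.fixture
def genome_factory(tmp_path):
    return lambda sequences: make_genome(tmp_path, sequences)


@pytest.fixture
def window_factory(tmp_path):
    return lambda window, **kw: window_genome(tmp_path, window, **kw)


def transcript(tid, exons, gene="G1", chrom="1", strand="+"):
    return TranscriptModel(tid, gene, chrom, strand, tuple(exons))


def gene(transcripts, gene_id="G1"):
    return GeneModel(gene_id, tuple(transcripts))


@pytest.fixture(scope="session")
def sim_small():
    """A 20-gene simulated dataset shared by read-only tests."""
    return simulate_all(SimConfig(seed=11, n_genes=20))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
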