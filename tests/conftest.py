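"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from nucleoguide.genome_model import GeneModel, Genome, PromoterRegion


def random_genome(rng: np.random.Generator, length: int, name: str = "chr1") -> Genome:
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return Genome({name: seq})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_genome(rng) -> Genome:
    return random_genome(rng, 2000)


@pytest.fixture
def whole_region(small_genome) -> PromoterRegion:
    chrom = next(iter(small_genome.sequences))
    return PromoterRegion(chrom, 0, small_genome.length(chrom), [], False)


@pytest.fixture
def plus_gene() -> GeneModel:
    return GeneModel("geneA", "chr1", "+", 1000, 1800, 1000)


def write_fasta(path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def write_gff3(path, rows: list[tuple[str, int, int, str, str]]) -> None:
    """rows: (chrom, start_1based, end_1based, strand, gene_id)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, s, e, strand, gid in rows:
            fh.write(f"{chrom}\tsrc\tgene\t{s}\t{e}\t.\t{strand}\t.\tID={gid}\n")
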