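"""Shared fixtures: small genomes, hit builders, random fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from ohnomap import AncestralGenome, GeneLocation, HitRecord


def make_hit(query: str, subject: str, bits: float, evalue: float = 1e-30) -> HitRecord:
    return HitRecord(
        query_protein=query, subject_protein=subject,
        bit_score=bits, e_value=evalue,
        query_gene=query, subject_gene=subject,
    )


def make_locations(spec: dict[str, list[str]], strand: str = "+") -> list[GeneLocation]:
    """spec: chromosome -> ordered gene ids; coordinates synthesised from order."""
    out = []
    for chrom, genes in spec.items():
        for rank, g in enumerate(genes):
            start = rank * 1000 + 1
            out.append(GeneLocation(g, chrom, start, start + 800, strand, rank))
    return out


def two_chromosome_ancestral(n_q: int = 400, n_u: int = 100) -> AncestralGenome:
    """A signal chromosome Q plus an unrelated chromosome U."""
    genes = {
        "Q": tuple(f"Q_g{i}" for i in range(n_q)),
        "U": tuple(f"U_g{i}" for i in range(n_u)),
    }
    strands = {g: "+" for gs in genes.values() for g in gs}
    return AncestralGenome(("Q", "U"), genes, strands)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
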