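"""Shared fixtures: tiny genomes and hand-built site tables."""

import numpy as np
import pandas as pd
import pytest

from methocc.io_formats import GenomeSequence
from methocc.meth_context import (
    DI_CATEGORIES,
    STRAND_CATEGORIES,
    TRI_CATEGORIES,
    classify_contexts,
)


@pytest.fixture
def toy_genome() -> GenomeSequence:
    return GenomeSequence(
        ["chr1", "chr2"],
        {"chr1": "ACACGTTACGGCACT", "chr2": "TTTCACCACGNNACG"},
    )


def build_sites(records) -> pd.DataFrame:
    """Site table from (chrom, pos, strand, di, tri, n_mod, n_total) tuples."""
    rows = list(records)
    df = pd.DataFrame(
        {
            "chrom": [r[0] for r in rows],
            "pos": np.array([r[1] for r in rows], dtype=np.int64),
            "strand": pd.Categorical([r[2] for r in rows], categories=STRAND_CATEGORIES),
            "di": pd.Categorical([r[3] for r in rows], categories=DI_CATEGORIES),
            "tri": pd.Categorical([r[4] for r in rows], categories=TRI_CATEGORIES),
            "count_modified": np.array([r[5] for r in rows], dtype=np.int32),
            "count_total": np.array([r[6] for r in rows], dtype=np.int32),
        }
    )
    with np.errstate(invalid="ignore"):
        df["level"] = np.where(
            df["count_total"] > 0,
            df["count_modified"] / df["count_total"].clip(lower=1),
            np.nan,
        )
    return df


@pytest.fixture
def random_genome_factory():
    """Random small genomes for property tests (seeded per call)."""

    def make(seed: int, length: int = 1000, n_frac: float = 0.0) -> GenomeSequence:
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        seq = rng.choice(bases, size=length)
        if n_frac > 0:
            seq[rng.random(length) < n_frac] = "N"
        return GenomeSequence(["chr1"], {"chr1": "".join(seq)})

    return make


@pytest.fixture
def covered_sites_factory(random_genome_factory):
    """Classified sites with random coverage/levels on a random genome."""

    def make(seed: int, length: int = 1000):
        genome = random_genome_factory(seed, length)
        sites = classify_contexts(genome)
        rng = np.random.default_rng(seed + 1)
        total = rng.poisson(10, size=len(sites)).astype(np.int32)
        mod = rng.binomial(total, rng.random(len(sites))).astype(np.int32)
        sites["count_total"] = total
        sites["count_modified"] = mod
        with np.errstate(invalid="ignore"):
            sites["level"] = np.where(total > 0, mod / np.maximum(total, 1), np.nan)
        return genome, sites

    return make
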