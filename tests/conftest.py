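"""Shared fixtures: small synthetic collections with planted truth.

Everything is generated at test time; nothing is read from disk fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest

from gutcatalog.cluster import cluster_species
from gutcatalog.io import GenomeRecord
from gutcatalog.synthetic import SimulationConfig, generate_collection


def random_genome(
    genome_id: str, length: int = 20_000, seed: int = 0, n_contigs: int = 1, **meta
) -> GenomeRecord:
    """One random genome, optionally split into equal contigs."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    step = length // n_contigs
    contigs = [
        (f"{genome_id}_c{i + 1}", seq[i * step : (i + 1) * step if i < n_contigs - 1 else length])
        for i in range(n_contigs)
    ]
    return GenomeRecord(genome_id=genome_id, contigs=contigs, **meta)


def mutate_genome(
    record: GenomeRecord, rate: float, seed: int = 0, genome_id: str | None = None
) -> tuple[GenomeRecord, list[tuple[str, int, str, str]]]:
    """Point-mutate a genome; returns the copy and (contig, pos0, ref, alt)."""
    rng = np.random.default_rng(seed)
    out = []
    muts = []
    for cid_old, seq in record.contigs:
        arr = np.array(list(seq))
        n = rng.binomial(len(seq), rate)
        positions = rng.choice(len(seq), size=n, replace=False)
        for p in positions:
            ref = arr[p]
            alt = [b for b in "ACGT" if b != ref][rng.integers(0, 3)]
            arr[p] = alt
            muts.append((cid_old, int(p), str(ref), alt))
        out.append((cid_old, "".join(arr)))
    gid = genome_id or record.genome_id + "_mut"
    new = GenomeRecord(genome_id=gid, contigs=[(f"{gid}_{c}", s) for c, s in out])
    return new, muts


@pytest.fixture(scope="session")
def small_collection():
    """3 species x 5 genomes, 30 kb, no degradation: exact truth mapping."""
    cfg = SimulationConfig(
        n_species=3,
        genomes_per_species=(5, 5),
        genome_length=30_000,
        incompleteness_range=(0.0, 0.0),
        contamination_prob=0.0,
        seed=101,
    )
    records, truth = generate_collection(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def small_clusters(small_collection):
    _, records, truth = small_collection
    clusters = cluster_species(records)
    by_id = {r.genome_id: r for r in records}
    return clusters, by_id, truth


@pytest.fixture(scope="session")
def degraded_collection():
    """3 species x 6 genomes with incompleteness and contamination on."""
    cfg = SimulationConfig(
        n_species=3,
        genomes_per_species=(6, 6),
        genome_length=30_000,
        incompleteness_range=(0.0, 0.10),
        contamination_prob=0.3,
        seed=202,
    )
    records, truth = generate_collection(cfg)
    return cfg, records, truth
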