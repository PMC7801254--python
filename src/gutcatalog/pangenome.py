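"""Protein clustering, per-species pan-genomes and catalog merging.

Protein catalogs are built by greedy incremental clustering: sequences are
sorted by length (descending) and each sequence joins the first existing
centroid it matches at the catalog identity over at least 80 % of the
shorter sequence, otherwise it founds a new cluster. Catalog identity
levels of interest are 1.0, 0.95, 0.90 and 0.50. Per-species pan-genomes
cluster conspecific proteins at 90 % identity; a gene cluster present in
>= 90 % of conspecific genomes is core, < 10 % is rare, everything between
is intermediate accessory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "B", "Z", "U", "O", "*"}


@dataclass
class ProteinSeq:
    seq_id: str
    genome_id: str
    species_id: str
    sequence: str


@dataclass
class ProteinCluster:
    cluster_id: str
    centroid_id: str
    members: list[ProteinSeq] = field(default_factory=list)
    identity: float = 0.9

    @property
    def size(self) -> int:
        return len(self.members)


def _check_sequence(p: ProteinSeq) -> None:
    bad = set(p.sequence.upper()) - AMINO_ACIDS
    if bad:
        raise ValueError(
            f"sequence {p.seq_id} contains non-amino-acid characters: {sorted(bad)}"
        )


def pair_identity_coverage(a: str, b: str) -> tuple[float, float]:
    """Identity and short-sequence coverage for one pair.

    The shorter sequence is aligned glocally (global on the shorter, local
    window on the longer); identity = matches / alignment columns,
    coverage = shorter-sequence residues aligned to a residue of the
    longer / length of the shorter.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    aln = edlib.align(short, long_, task="path", mode="HW")
    if aln["editDistance"] < 0:
        return 0.0, 0.0
    n_match = n_cols = n_both = 0
    for count, op in _cigar_ops(aln["cigar"]):
        n_cols += count
        if op == "=":
            n_match += count
            n_both += count
        elif op == "X":
            n_both += count
    if n_cols == 0:
        return 0.0, 0.0
    return n_match / n_cols, n_both / len(short)


def _cigar_ops(cigar: str):
    count = 0
    for ch in cigar:
        if ch.isdigit():
            count = count * 10 + int(ch)
        else:
            yield count, ch
            count = 0


def cluster_proteins(
    sequences: Iterable[ProteinSeq],
    identity: float,
    coverage: float = 0.8,
    min_length: int = 10,
) -> list[ProteinCluster]:
    """Greedy incremental clustering at the given identity/coverage.

    Deterministic: input order is irrelevant because sequences are sorted
    by (length desc, seq_id) before clustering. The sum of cluster sizes
    always equals the number of input sequences.
    """
    seqs = sorted(sequences, key=lambda p: (-len(p.sequence), p.seq_id))
    for p in seqs:
        _check_sequence(p)
        if len(p.sequence) < min_length:
            raise ValueError(f"sequence {p.seq_id} shorter than {min_length} aa")
    clusters: list[ProteinCluster] = []
    centroids: list[str] = []
    for p in seqs:
        placed = False
        for cl, cent in zip(clusters, centroids):
            # coverage of the shorter sequence can never reach the cutoff
            # when the length ratio is below it
            if len(p.sequence) / len(cent) < coverage * 0.99:
                continue
            ident, cov = pair_identity_coverage(p.sequence, cent)
            if ident >= identity and cov >= coverage:
                cl.members.append(p)
                placed = True
                break
        if not placed:
            clusters.append(
                ProteinCluster(
                    cluster_id=f"cluster_{len(clusters) + 1:06d}",
                    centroid_id=p.seq_id,
                    members=[p],
                    identity=identity,
                )
            )
            centroids.append(p.sequence)
    return clusters


@dataclass
class PanGenome:
    species_id: str
    presence: pd.DataFrame  # gene cluster x genome, boolean
    frequency_class: pd.Series  # "core" | "intermediate" | "rare" per cluster

    @property
    def n_clusters(self) -> int:
        return len(self.presence)

    def class_counts(self) -> pd.Series:
        return self.frequency_class.value_counts()


def classify_frequency(presence_fraction: float) -> str:
    if presence_fraction >= 0.90:
        return "core"
    if presence_fraction < 0.10:
        return "rare"
    return "intermediate"


def build_pangenome(
    species_id: str,
    member_proteins: dict[str, list[ProteinSeq]],
    identity: float = 0.90,
    coverage: float = 0.8,
    profile: str | None = None,
    completeness: dict[str, float] | None = None,
    min_genomes_intraspecies: int = 10,
) -> PanGenome | None:
    """Cluster conspecific proteins and build the presence matrix.

    ``member_proteins`` maps genome_id -> protein list. Multiple members
    of a gene cluster from one genome count once in the presence matrix
    (no paralog splitting). The "intraspecies" profile admits only
    near-complete genomes (completeness >= 90) and requires at least
    ``min_genomes_intraspecies`` of them, returning None (with the reason
    left to the caller's log) when the species fails the gate.
    """
    genomes = sorted(member_proteins)
    if profile == "intraspecies":
        if completeness is None:
            raise ValueError("intraspecies profile requires completeness values")
        genomes = [g for g in genomes if completeness.get(g, 0.0) >= 90.0]
        if len(genomes) < min_genomes_intraspecies:
            return None
    if not genomes:
        return None
    seqs = [p for g in genomes for p in member_proteins[g]]
    clusters = cluster_proteins(seqs, identity=identity, coverage=coverage)
    data = {
        cl.cluster_id: [
            any(m.genome_id == g for m in cl.members) for g in genomes
        ]
        for cl in clusters
    }
    presence = pd.DataFrame(data, index=genomes).T
    frac = presence.mean(axis=1)
    freq = frac.map(classify_frequency)
    return PanGenome(species_id=species_id, presence=presence, frequency_class=freq)


def normalized_pangenome_size(pangenome: PanGenome, representative_gene_count: int) -> float:
    """Total core+accessory gene clusters over the representative's gene count."""
    if representative_gene_count < 1:
        raise ValueError("representative gene count must be >= 1")
    return pangenome.n_clusters / representative_gene_count


def hq_subset(catalog: Sequence[ProteinCluster]) -> list[ProteinCluster]:
    """Clusters supported by >= 2 proteins from different genomes of the
    same species."""
    out = []
    for cl in catalog:
        by_species: dict[str, set[str]] = {}
        for m in cl.members:
            by_species.setdefault(m.species_id, set()).add(m.genome_id)
        if any(len(gs) >= 2 for gs in by_species.values()):
            out.append(cl)
    return out


@dataclass(frozen=True)
class MergeStats:
    total: int
    overlap: int
    pct_increase: int
    pct_b_covered: float


def merge_percent_increase(baseline_clusters: int, merged_total: int) -> int:
    """(total - baseline) / baseline x 100, rounded to the nearest integer."""
    if baseline_clusters < 1:
        raise ValueError("baseline catalog is empty")
    return round((merged_total - baseline_clusters) / baseline_clusters * 100)


def merge_catalogs(
    catalog_a: Sequence[ProteinSeq],
    catalog_b: Sequence[ProteinSeq],
    identity: float = 0.90,
    coverage: float = 0.8,
) -> MergeStats:
    """Co-cluster the centroids of two catalogs and report merge statistics.

    ``overlap`` counts merged clusters containing centroids from both
    catalogs; ``pct_increase`` is the percent growth of the merged total
    over catalog B; ``pct_b_covered`` the share of B's centroids that fall
    in shared clusters.
    """
    if not catalog_a or not catalog_b:
        raise ValueError("cannot merge an empty catalog")
    tagged = [
        ProteinSeq(f"A|{p.seq_id}", p.genome_id, p.species_id, p.sequence)
        for p in catalog_a
    ] + [
        ProteinSeq(f"B|{p.seq_id}", p.genome_id, p.species_id, p.sequence)
        for p in catalog_b
    ]
    merged = cluster_proteins(tagged, identity=identity, coverage=coverage)
    overlap = sum(
        1
        for cl in merged
        if {m.seq_id[0] for m in cl.members} == {"A", "B"}
    )
    n_b = len(catalog_b)
    shared_b = sum(
        sum(1 for m in cl.members if m.seq_id.startswith("B|"))
        for cl in merged
        if {m.seq_id[0] for m in cl.members} == {"A", "B"}
    )
    return MergeStats(
        total=len(merged),
        overlap=overlap,
        pct_increase=merge_percent_increase(n_b, len(merged)),
        pct_b_covered=100.0 * shared_b / n_b,
    )
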