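"""Species-level clustering, dereplication, dendrograms and cultured status.

Clustering is two-stage: a recall-oriented primary grouping by
single-linkage on Mash distances (threshold 0.10), then greedy secondary
clustering inside each primary group at ANI >= 95 % over >= 30 % alignment
fraction. Genomes are ranked by representative score with isolates always
ahead of MAGs, the highest-ranked unassigned genome seeds a cluster, and
the seed becomes the cluster representative. Collections larger than a
chunk size are shuffled into chunks, clustered independently, the chunk
representatives pooled and re-clustered, and every non-representative
genome follows its chunk representative into the final cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import comb

from .io import GenomeRecord
from .qc import representative_score
from .sketch import (
    ANIResult,
    FragmentIndex,
    SketchProfile,
    ani_af,
    build_sketch,
    mash_distance,
)

CULTURED_IN_COLLECTION = "cultured_in_collection"
CULTURED_EXTERNAL = "cultured_external_match"
UNCULTURED = "uncultured"


@dataclass
class SpeciesCluster:
    species_id: str
    representative_id: str
    member_ids: list[str]
    nonredundant_ids: list[str] = field(default_factory=list)
    cultured_status: str = UNCULTURED

    def __post_init__(self):
        assert self.representative_id in self.member_ids


def _rank_key(record: GenomeRecord) -> tuple:
    """Isolates outrank all MAGs; then representative score desc; ties by
    genome_id for determinism."""
    score = representative_score(
        record.completeness, record.contamination, max(record.n50, 1)
    )
    return (0 if record.genome_type == "isolate" else 1, -score, record.genome_id)


def _sketches(genomes: Sequence[GenomeRecord], cache: dict) -> list[SketchProfile]:
    out = []
    for g in genomes:
        if g.genome_id not in cache:
            cache[g.genome_id] = build_sketch(g)
        out.append(cache[g.genome_id])
    return out


def mash_distance_matrix(sketches: Sequence[SketchProfile]) -> np.ndarray:
    n = len(sketches)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = mash_distance(sketches[i], sketches[j])
    return dm


def _primary_groups(
    genomes: Sequence[GenomeRecord], sketches: Sequence[SketchProfile], threshold: float
) -> list[list[int]]:
    """Single-linkage groups at mash distance <= threshold (indices)."""
    n = len(genomes)
    if n == 1:
        return [[0]]
    dm = mash_distance_matrix(sketches)
    labels = fcluster(linkage(squareform(dm, checks=False), method="single"),
                      t=threshold, criterion="distance")
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    return list(groups.values())


def _greedy_secondary(
    genomes: list[GenomeRecord],
    ani_threshold: float,
    af_threshold: float,
    fragment_len: int,
) -> list[tuple[str, list[str]]]:
    """Greedy clustering within a primary group.

    Returns (representative_id, member_ids) tuples. The best-ranked
    unassigned genome seeds a cluster; every unassigned genome at
    ANI >= threshold and AF >= threshold to the seed joins it.
    """
    order = sorted(genomes, key=_rank_key)
    unassigned = list(order)
    out = []
    while unassigned:
        seed = unassigned.pop(0)
        members = [seed.genome_id]
        index = FragmentIndex.build(seed)
        rest = []
        for g in unassigned:
            r: ANIResult = ani_af(g, seed, fragment_len=fragment_len, index=index)
            if r.ani is not None and r.ani >= ani_threshold and r.af >= af_threshold:
                members.append(g.genome_id)
            else:
                rest.append(g)
        unassigned = rest
        out.append((seed.genome_id, members))
    return out


def cluster_species(
    genomes: Sequence[GenomeRecord],
    primary_distance: float = 0.10,
    ani_threshold: float = 95.0,
    af_threshold: float = 0.30,
    chunk_size: int | None = None,
    seed: int = 0,
    fragment_len: int = 1000,
    _sketch_cache: dict | None = None,
) -> list[SpeciesCluster]:
    """Two-stage species clustering with optional chunked iteration.

    With ``chunk_size`` set and exceeded, genomes are shuffled (seeded),
    chunks clustered independently, chunk representatives pooled and
    re-clustered, and members reassigned to their representative's final
    cluster.
    """
    genomes = list(genomes)
    if not genomes:
        return []
    cache = _sketch_cache if _sketch_cache is not None else {}

    if chunk_size is not None and len(genomes) > chunk_size:
        rng = np.random.default_rng(seed)
        shuffled = [genomes[i] for i in rng.permutation(len(genomes))]
        follower: dict[str, list[str]] = {}
        reps: list[GenomeRecord] = []
        by_id = {g.genome_id: g for g in genomes}
        for start in range(0, len(shuffled), chunk_size):
            chunk = shuffled[start : start + chunk_size]
            for cl in cluster_species(
                chunk, primary_distance, ani_threshold, af_threshold,
                chunk_size=None, fragment_len=fragment_len, _sketch_cache=cache,
            ):
                follower[cl.representative_id] = cl.member_ids
                reps.append(by_id[cl.representative_id])
        pooled = cluster_species(
            reps, primary_distance, ani_threshold, af_threshold,
            chunk_size=None, fragment_len=fragment_len, _sketch_cache=cache,
        )
        final = []
        for cl in pooled:
            members: list[str] = []
            for rep in cl.member_ids:
                members.extend(follower[rep])
            final.append(
                SpeciesCluster(cl.species_id, cl.representative_id, sorted(members))
            )
        return _renumber(final)

    sketches = _sketches(genomes, cache)
    clusters: list[SpeciesCluster] = []
    for group in _primary_groups(genomes, sketches, primary_distance):
        subset = [genomes[i] for i in group]
        for rep_id, member_ids in _greedy_secondary(
            subset, ani_threshold, af_threshold, fragment_len
        ):
            clusters.append(SpeciesCluster("", rep_id, sorted(member_ids)))
    return _renumber(clusters)


def _renumber(clusters: list[SpeciesCluster]) -> list[SpeciesCluster]:
    """Stable species ids: clusters sorted by representative_id."""
    clusters = sorted(clusters, key=lambda c: c.representative_id)
    for i, cl in enumerate(clusters, start=1):
        cl.species_id = f"species_{i:04d}"
    return clusters


def dereplicate_conspecific(
    cluster: SpeciesCluster,
    genomes: dict[str, GenomeRecord],
    mash_threshold: float = 0.001,
    _sketch_cache: dict | None = None,
) -> list[str]:
    """Nonredundant conspecific member set.

    Greedy score-ordered collapse of members within mash distance 0.001
    of an already-retained genome (0.001 corresponds to 99.9 % nucleotide
    identity), followed by per-sample uniqueness: at most one genome per
    (species, sample) counts toward species frequency.
    """
    cache = _sketch_cache if _sketch_cache is not None else {}
    members = sorted((genomes[m] for m in cluster.member_ids), key=_rank_key)
    sketches = {g.genome_id: s for g, s in zip(members, _sketches(members, cache))}
    retained: list[GenomeRecord] = []
    for g in members:
        if all(
            mash_distance(sketches[g.genome_id], sketches[r.genome_id]) > mash_threshold
            for r in retained
        ):
            retained.append(g)
    seen_samples: set[str] = set()
    nonredundant = []
    for g in retained:  # still score-ordered
        key = g.sample_id or g.genome_id
        if key in seen_samples:
            continue
        seen_samples.add(key)
        nonredundant.append(g.genome_id)
    return sorted(nonredundant)


def complete_linkage_clusters(dm: np.ndarray, cutoff: float) -> np.ndarray:
    """Flat cluster labels from complete-linkage clustering of a distance
    matrix, cutting the dendrogram at ``cutoff``."""
    Z = linkage(squareform(dm, checks=False), method="complete")
    return fcluster(Z, t=cutoff, criterion="distance")


def intraspecies_dendrogram(
    cluster: SpeciesCluster,
    genomes: dict[str, GenomeRecord],
    cutoffs: Sequence[float] = (0.03, 0.01),
    _sketch_cache: dict | None = None,
) -> dict[float, int]:
    """Complete-linkage cluster counts at each mash-distance cutoff.

    Cutoff 0.03 corresponds to ~97 % ANI and 0.01 to ~99 % ANI. Singleton
    species report 1 cluster at every cutoff by convention.
    """
    members = [genomes[m] for m in sorted(cluster.member_ids)]
    if len(members) < 2:
        return {c: 1 for c in cutoffs}
    cache = _sketch_cache if _sketch_cache is not None else {}
    dm = mash_distance_matrix(_sketches(members, cache))
    return {
        c: int(complete_linkage_clusters(dm, c).max()) for c in cutoffs
    }


def assign_cultured_status(
    cluster: SpeciesCluster,
    genomes: dict[str, GenomeRecord],
    external_isolate_refs: Sequence[GenomeRecord] = (),
    ani_threshold: float = 95.0,
    af_threshold: float = 0.30,
) -> str:
    """Cultured if the cluster contains an isolate, else if its
    representative matches an external isolate reference at >= 95 % ANI
    over >= 30 % of the representative's genome length, else uncultured.

    The alignment fraction here is anchored on the representative (query
    coverage), matching the whole-genome-alignment convention for
    reference screens rather than the "larger" mode used in clustering.
    """
    if any(genomes[m].genome_type == "isolate" for m in cluster.member_ids):
        return CULTURED_IN_COLLECTION
    rep = genomes[cluster.representative_id]
    for ref in external_isolate_refs:
        r = ani_af(rep, ref, coverage_mode="query")
        if r.ani is not None and r.ani >= ani_threshold and r.af >= af_threshold:
            return CULTURED_EXTERNAL
    return UNCULTURED


def compare_clusterings(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions of the same genomes.

    ``labels_a``/``labels_b`` are mappings genome_id -> cluster label (or
    equal-length sequences). Computed from the pair-counting contingency
    table; 1.0 for identical partitions, ~0 for random agreement.
    """
    if isinstance(labels_a, dict) or isinstance(labels_b, dict):
        if set(labels_a) != set(labels_b):
            raise ValueError("partitions cover different genome sets")
        keys = sorted(labels_a)
        a = [labels_a[k] for k in keys]
        b = [labels_b[k] for k in keys]
    else:
        a, b = list(labels_a), list(labels_b)
        if len(a) != len(b):
            raise ValueError("partitions cover different genome sets")
    ct = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    sum_comb = comb(ct, 2).sum()
    sum_a = comb(ct.sum(axis=1), 2).sum()
    sum_b = comb(ct.sum(axis=0), 2).sum()
    n_pairs = comb(ct.sum(), 2)
    expected = sum_a * sum_b / n_pairs if n_pairs else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def membership_table(clusters: Sequence[SpeciesCluster]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": m,
            "species_id": cl.species_id,
            "representative_id": cl.representative_id,
            "is_representative": m == cl.representative_id,
        }
        for cl in clusters
        for m in cl.member_ids
    ]
    return pd.DataFrame(rows).sort_values("genome_id").reset_index(drop=True)
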