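"""Geographic diversity, rarefaction, classification improvement and
phylogenetic diversity.

Geographic diversity of a species is the Shannon index (natural log) over
the per-continent proportions of samples containing it, so a species found
on all continents at similar prevalence scores highest (H = ln 6 for a
uniform six-continent profile). Rarefaction curves give the expected
number of distinct species as a function of the number of nonredundant
genomes sampled, averaged over seeded random permutations. Phylogenetic
diversity (PD) is the sum of branch lengths; the share exclusive to
uncultured species is PD_total - PD_cultured, where PD_cultured sums the
branches of the subtree spanning the cultured leaves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import skbio


@dataclass
class GeoProfile:
    species_id: str
    continent_fractions: dict[str, float]
    shannon_index: float


def shannon_index(proportions, renormalize: bool = True) -> float:
    """H = -sum p ln p over strictly positive proportions.

    With ``renormalize`` (default) the positive proportions are scaled to
    sum to 1 first, so the index depends on evenness across continents
    where the species occurs, not on absolute prevalence.
    """
    p = np.asarray([x for x in proportions if x > 0], dtype=float)
    if p.size == 0:
        raise ValueError("species absent from all samples")
    if renormalize:
        p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def geographic_diversity(
    species_id: str,
    species_presence_by_sample: set[str],
    sample_continent_map: dict[str, str],
    renormalize: bool = True,
) -> GeoProfile:
    """Shannon diversity over per-continent sample prevalence.

    ``species_presence_by_sample`` is the set of samples containing the
    species; every sample must appear in ``sample_continent_map``.
    """
    missing = species_presence_by_sample - set(sample_continent_map)
    if missing:
        raise ValueError(f"samples with no continent mapping: {sorted(missing)}")
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    for sample, cont in sample_continent_map.items():
        totals[cont] = totals.get(cont, 0) + 1
        if sample in species_presence_by_sample:
            hits[cont] = hits.get(cont, 0) + 1
    fractions = {c: hits.get(c, 0) / totals[c] for c in sorted(totals)}
    return GeoProfile(
        species_id=species_id,
        continent_fractions=fractions,
        shannon_index=shannon_index(fractions.values(), renormalize=renormalize),
    )


def rarefaction_curve(
    species_labels,
    n_reps: int = 100,
    seed: int = 0,
    exclude_singletons: bool = False,
) -> np.ndarray:
    """Expected distinct-species count at each genome depth 1..N.

    ``species_labels`` holds one species label per nonredundant genome.
    The curve is the mean over ``n_reps`` seeded random genome orderings
    of the cumulative number of distinct species. With
    ``exclude_singletons``, species represented by a single genome are
    removed before permuting.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels = np.asarray(list(species_labels))
    if exclude_singletons:
        uniq, counts = np.unique(labels, return_counts=True)
        keep = set(uniq[counts > 1])
        labels = np.asarray([l for l in labels if l in keep])
    n = labels.size
    if n == 0:
        return np.zeros(0)
    _, codes = np.unique(labels, return_inverse=True)
    n_species = codes.max() + 1
    rng = np.random.default_rng(seed)
    acc = np.zeros(n)
    for _ in range(n_reps):
        perm = codes[rng.permutation(n)]
        # a species counts toward the curve at its first occurrence
        first_at = np.full(n_species, n, dtype=np.int64)
        np.minimum.at(first_at, perm, np.arange(n))
        gains = np.zeros(n, dtype=np.int64)
        np.add.at(gains, first_at[first_at < n], 1)
        acc += np.cumsum(gains)
    return acc / n_reps


def rarefaction_expectation(species_counts, depths) -> np.ndarray:
    """Closed-form expectation E[S_n] = sum_s (1 - C(N-N_s, n)/C(N, n)).

    Exact hypergeometric mean of the rarefaction curve, used as the
    analytic counterpart of the permutation estimate.
    """
    from scipy.special import gammaln

    counts = np.asarray(list(species_counts), dtype=np.int64)
    N = counts.sum()

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = []
    for n in depths:
        terms = []
        for Ns in counts:
            if N - Ns < n:
                terms.append(1.0)
            else:
                terms.append(1.0 - math.exp(log_comb(N - Ns, n) - log_comb(N, n)))
        out.append(sum(terms))
    return np.asarray(out)


def classification_improvement(p_new: float, p_ref: float) -> float:
    """(p_new - p_ref) / p_ref x 100; undefined when p_ref is zero."""
    if p_ref == 0:
        raise ValueError("reference classification proportion is zero")
    return (p_new - p_ref) / p_ref * 100.0


@dataclass
class PDResult:
    pd_total: float
    pd_cultured: float
    pd_exclusive: float
    uncultured_monophyletic_groups: list[tuple[int, list[str]]] = field(
        default_factory=list
    )


def phylogenetic_diversity(
    tree: skbio.TreeNode, cultured_labels: dict[str, bool]
) -> PDResult:
    """PD accounting on a supplied tree.

    ``cultured_labels`` maps every leaf name to True (cultured) or False.
    PD_total is the sum of all branch lengths. PD_cultured sums the
    branches on paths between cultured leaves (the spanning subtree; the
    root branch is excluded unless it lies on such a path, which it never
    does). PD_exclusive = PD_total - PD_cultured. Uncultured monophyletic
    groups are the maximal internal nodes whose leaves are all uncultured,
    reported as (size, sorted leaf names).
    """
    leaves = list(tree.tips())
    unlabeled = [t.name for t in leaves if t.name not in cultured_labels]
    if unlabeled:
        raise ValueError(f"unlabeled leaves: {unlabeled}")
    for node in tree.traverse(include_self=True):
        if node is not tree and node.length is None:
            raise ValueError("branch lengths required for PD")

    n_cultured_total = sum(1 for t in leaves if cultured_labels[t.name])
    pd_total = sum(n.length or 0.0 for n in tree.traverse(include_self=True))

    # per-node cultured-leaf counts (postorder)
    counts: dict[int, int] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            counts[id(node)] = 1 if cultured_labels[node.name] else 0
        else:
            counts[id(node)] = sum(counts[id(c)] for c in node.children)

    pd_cultured = 0.0
    for node in tree.traverse(include_self=False):
        below = counts[id(node)]
        # edge is on a path between cultured leaves iff both sides hold one
        if 0 < below < n_cultured_total:
            pd_cultured += node.length or 0.0

    groups: list[tuple[int, list[str]]] = []

    def walk(node):
        if node.is_tip():
            return
        if counts[id(node)] == 0:
            names = sorted(t.name for t in node.tips())
            groups.append((len(names), names))
            return  # maximal: do not descend
        for c in node.children:
            if c.is_tip():
                continue
            walk(c)

    walk(tree)
    return PDResult(
        pd_total=pd_total,
        pd_cultured=pd_cultured,
        pd_exclusive=pd_total - pd_cultured,
        uncultured_monophyletic_groups=sorted(groups, key=lambda g: (-g[0], g[1])),
    )
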