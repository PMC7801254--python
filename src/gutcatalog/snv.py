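"""Intraspecies SNV catalog construction.

Conspecific genomes are aligned to their species representative by exact
k-mer anchoring (diagonal grouping on both strands) with inter-anchor and
flank gaps closed by banded alignment; overlapping blocks are reduced to a
one-to-one mapping on both the representative and member axes, emulating
the query/reference uniqueness filtering of whole-genome aligners. Every
aligned column with differing, non-gap bases is a substitution; insertions
and deletions of any length are never counted as SNVs. A locus enters the
species catalog only when the same alternate allele is carried by at least
two conspecific genomes, with coordinates unified on the representative
genome (1-based, forward strand). Catalog entries are flagged continent-
or genome-type-specific when all carriers share one continent or type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import edlib
import numpy as np
import pandas as pd

from .cluster import SpeciesCluster, _rank_key
from .io import GenomeRecord
from .sketch import _codes, _kmer_ints, reverse_complement

ANCHOR_K = 19


@dataclass
class AlignmentBlock:
    """One collinear aligned block between a member and the representative.

    Column data is stored as parallel arrays over aligned-both columns
    (gap columns are never recorded): ``rep_cols``/``mem_cols`` are 0-based
    positions, mismatches are indexed into them.
    """

    rep_contig: str
    member_contig: str
    strand: str  # "+" | "-"
    rep_cols: np.ndarray
    mem_cols: np.ndarray
    mis_idx: np.ndarray  # indices into rep_cols/mem_cols
    mis_ref: np.ndarray  # dtype U1
    mis_alt: np.ndarray

    @property
    def n_aligned(self) -> int:
        return int(self.rep_cols.size)

    @property
    def n_match(self) -> int:
        return self.n_aligned - int(self.mis_idx.size)

    @property
    def rep_interval(self) -> tuple[int, int]:
        """1-based closed interval on the representative contig."""
        return int(self.rep_cols.min()) + 1, int(self.rep_cols.max()) + 1

    @property
    def member_interval(self) -> tuple[int, int]:
        return int(self.mem_cols.min()) + 1, int(self.mem_cols.max()) + 1


@dataclass(frozen=True)
class Substitution:
    rep_contig: str
    position: int  # 1-based on representative forward strand
    ref: str
    alt: str


@dataclass
class SNVRecord:
    species_id: str
    rep_contig: str
    position: int
    ref: str
    alt: str
    carriers: list[str]
    continents: set[str] = field(default_factory=set)
    genome_types: set[str] = field(default_factory=set)
    continent_specific: bool = False
    type_specific: bool = False


class AnchorIndex:
    """Exact k-mer position index over the representative genome."""

    def __init__(self, rep: GenomeRecord, k: int = ANCHOR_K):
        self.k = k
        self.rep = rep
        self.contig_names = [cid for cid, _ in rep.contigs]
        self.contig_seqs = {cid: seq for cid, seq in rep.contigs}
        self.positions: dict[int, list[tuple[int, int]]] = {}
        for ci, (_, seq) in enumerate(rep.contigs):
            ints, valid = _kmer_ints(_codes(seq), k)
            for pos in np.nonzero(valid)[0]:
                self.positions.setdefault(int(ints[pos]), []).append((ci, int(pos)))


def _anchor_groups(matches: list[tuple[int, int]], band: int = 100, min_anchors: int = 2):
    """Split (member_pos, rep_pos) matches into collinear diagonal groups."""
    if not matches:
        return
    matches = sorted(matches, key=lambda t: (t[1] - t[0], t[0]))
    group = [matches[0]]
    for m in matches[1:]:
        if (m[1] - m[0]) - (group[-1][1] - group[-1][0]) > band:
            if len(group) >= min_anchors:
                yield group
            group = [m]
        else:
            group.append(m)
    if len(group) >= min_anchors:
        yield group


def _smooth_columns(cols: list[tuple[str | None, str | None]], window: int = 40):
    """Re-pair balanced insertion/deletion runs into substitution columns.

    Pure edit distance cannot prefer two substitutions over an equal-cost
    insertion+deletion pair, so nearby substitutions sometimes surface as
    balanced gaps. Whenever a gap opens and the opposite gap rebalances it
    within ``window`` columns, the stretch is re-paired column by column
    (both sides consume the same number of bases, so the pairing is
    exact). Unbalanced gaps — true indels of any length — are preserved.
    """
    out: list[tuple[str | None, str | None]] = []
    i = 0
    n = len(cols)
    while i < n:
        qc, tc = cols[i]
        if qc is None or tc is None:
            qseg: list[str] = []
            tseg: list[str] = []
            end = None
            j = i
            while j < n and j - i < window:
                q2, t2 = cols[j]
                if q2 is not None:
                    qseg.append(q2)
                if t2 is not None:
                    tseg.append(t2)
                if qseg and len(qseg) == len(tseg):
                    end = j
                    break
                j += 1
            if end is not None:
                out.extend(zip(qseg, tseg))
                i = end + 1
                continue
        out.append(cols[i])
        i += 1
    return out


def _extend_group(
    group, mem_seq: str, rep_seq: str, strand: str, mem_len: int, k: int, pad: int = 200
):
    """Close gaps in one anchor group with a banded infix alignment and
    emit column arrays in representative/original-member coordinates.

    Flanks beyond the outermost anchors are extended along the anchor
    diagonal but never past the representative contig, so member sequence
    that belongs elsewhere (a neighboring contig of the original genome)
    cannot be forced into the window.
    """
    m_anchor_lo = min(m for m, _ in group)
    m_anchor_hi = max(m for m, _ in group) + k
    r_anchor_lo = min(r for _, r in group)
    r_anchor_hi = max(r for _, r in group) + k
    left = min(pad, m_anchor_lo, r_anchor_lo)
    right = min(pad, mem_len - m_anchor_hi, len(rep_seq) - r_anchor_hi)
    mlo = m_anchor_lo - left
    mhi = m_anchor_hi + right
    slack = 50  # indel drift allowance for the rep window
    rlo = max(0, r_anchor_lo - left - slack)
    rhi = min(len(rep_seq), r_anchor_hi + right + slack)
    q = mem_seq[mlo:mhi]
    t = rep_seq[rlo:rhi]
    aln = edlib.align(q, t, task="path", mode="HW")
    if aln["editDistance"] < 0 or not aln["cigar"]:
        return None

    # raw alignment columns as (member char | None, rep char | None)
    cols: list[tuple[str | None, str | None]] = []
    tpos = aln["locations"][0][0]
    qpos = 0
    count = 0
    for ch in aln["cigar"]:
        if ch.isdigit():
            count = count * 10 + int(ch)
            continue
        op, nrun = ch, count
        count = 0
        if op in "=X":
            cols.extend((q[qpos + i], t[tpos + i]) for i in range(nrun))
            qpos += nrun
            tpos += nrun
        elif op == "I":  # extra member bases
            cols.extend((q[qpos + i], None) for i in range(nrun))
            qpos += nrun
        elif op == "D":  # missing member bases
            cols.extend((None, t[tpos + i]) for i in range(nrun))
            tpos += nrun
    cols = _smooth_columns(cols)

    rep_cols: list[int] = []
    mem_cols: list[int] = []
    mis: list[tuple[int, str, str]] = []  # (column index, ref, alt)
    tpos = rlo + aln["locations"][0][0]
    qpos = mlo
    for qc, tc in cols:
        if qc is not None and tc is not None:
            rep_cols.append(tpos)
            mem_cols.append(qpos)
            if qc != tc:
                mis.append((len(rep_cols) - 1, tc, qc))
            tpos += 1
            qpos += 1
        elif qc is not None:
            qpos += 1
        else:
            tpos += 1
    if not rep_cols:
        return None
    rep_arr = np.asarray(rep_cols, dtype=np.int64)
    mem_local = np.asarray(mem_cols, dtype=np.int64)
    if strand == "-":
        mem_arr = mem_len - 1 - mem_local
    else:
        mem_arr = mem_local
    return (
        rep_arr,
        mem_arr,
        np.asarray([i for i, _, _ in mis], dtype=np.int64),
        np.asarray([r for _, r, _ in mis], dtype="U1"),
        np.asarray([a for _, _, a in mis], dtype="U1"),
    )


def align_to_representative(
    member: GenomeRecord,
    representative: GenomeRecord,
    index: AnchorIndex | None = None,
    k: int = ANCHOR_K,
    anchor_step: int = 4,
    max_overlap_fraction: float = 0.5,
) -> list[AlignmentBlock]:
    """Anchor-chain-and-extend alignment of a member to the representative.

    Returns one-to-one filtered blocks: for overlapping candidates the
    highest-scoring block wins on both axes and lower-scoring blocks are
    trimmed to unclaimed positions (dropped entirely when more than
    ``max_overlap_fraction`` of their columns are already claimed).
    """
    if index is None:
        index = AnchorIndex(representative, k)
    candidates: list[AlignmentBlock] = []
    for mem_cid, mem_seq in member.contigs:
        mem_len = len(mem_seq)
        for strand, seq in (("+", mem_seq), ("-", reverse_complement(mem_seq))):
            ints, valid = _kmer_ints(_codes(seq), index.k)
            per_contig: dict[int, list[tuple[int, int]]] = {}
            for mpos in range(0, ints.size, anchor_step):
                if not valid[mpos]:
                    continue
                for ci, rpos in index.positions.get(int(ints[mpos]), ()):
                    per_contig.setdefault(ci, []).append((mpos, rpos))
            for ci, matches in per_contig.items():
                rep_cid = index.contig_names[ci]
                rep_seq = index.contig_seqs[rep_cid]
                for group in _anchor_groups(matches):
                    ext = _extend_group(group, seq, rep_seq, strand, mem_len, index.k)
                    if ext is None:
                        continue
                    rep_arr, mem_arr, mi, mr, ma = ext
                    candidates.append(
                        AlignmentBlock(rep_cid, mem_cid, strand, rep_arr, mem_arr, mi, mr, ma)
                    )
    return _one_to_one_filter(candidates, index, member, max_overlap_fraction)


def _one_to_one_filter(
    candidates: list[AlignmentBlock],
    index: AnchorIndex,
    member: GenomeRecord,
    max_overlap_fraction: float,
) -> list[AlignmentBlock]:
    """Greedy uniqueness filter: each representative base and each member
    base belongs to at most one retained block."""
    rep_taken = {cid: np.zeros(len(seq), dtype=bool) for cid, seq in index.rep.contigs}
    mem_taken = {cid: np.zeros(len(seq), dtype=bool) for cid, seq in member.contigs}
    kept: list[AlignmentBlock] = []
    for blk in sorted(candidates, key=lambda b: -b.n_match):
        free = ~(rep_taken[blk.rep_contig][blk.rep_cols] | mem_taken[blk.member_contig][blk.mem_cols])
        if blk.n_aligned == 0 or free.sum() < blk.n_aligned * (1 - max_overlap_fraction):
            continue
        if not free.all():
            keep_col = np.nonzero(free)[0]
            remap = {int(c): i for i, c in enumerate(keep_col)}
            keep_mis = np.asarray(
                [i for i, c in enumerate(blk.mis_idx) if int(c) in remap], dtype=np.int64
            )
            blk = AlignmentBlock(
                blk.rep_contig,
                blk.member_contig,
                blk.strand,
                blk.rep_cols[keep_col],
                blk.mem_cols[keep_col],
                np.asarray([remap[int(blk.mis_idx[i])] for i in keep_mis], dtype=np.int64),
                blk.mis_ref[keep_mis] if keep_mis.size else blk.mis_ref[:0],
                blk.mis_alt[keep_mis] if keep_mis.size else blk.mis_alt[:0],
            )
        rep_taken[blk.rep_contig][blk.rep_cols] = True
        mem_taken[blk.member_contig][blk.mem_cols] = True
        kept.append(blk)
    return kept


def call_snvs(blocks: Sequence[AlignmentBlock]) -> list[Substitution]:
    """Substitutions from one-to-one blocks.

    Only aligned columns with both bases present and differing are
    emitted; indel columns were never recorded in the blocks, so single-
    and multi-base insertions/deletions can never yield an SNV.
    """
    out = []
    for blk in blocks:
        for i in range(blk.mis_idx.size):
            col = int(blk.mis_idx[i])
            out.append(
                Substitution(
                    rep_contig=blk.rep_contig,
                    position=int(blk.rep_cols[col]) + 1,
                    ref=str(blk.mis_ref[i]),
                    alt=str(blk.mis_alt[i]),
                )
            )
    return out


def aligned_rep_bases(blocks: Sequence[AlignmentBlock]) -> int:
    return int(sum(b.n_aligned for b in blocks))


def build_species_snv_catalog(
    cluster: SpeciesCluster,
    genomes: dict[str, GenomeRecord],
    min_members: int = 3,
    min_carriers: int = 2,
) -> list[SNVRecord] | None:
    """Unified SNV catalog of one species, or None when the species has
    fewer than ``min_members`` conspecific genomes."""
    if len(cluster.member_ids) < min_members:
        return None
    rep = genomes[cluster.representative_id]
    index = AnchorIndex(rep)
    carriers: dict[tuple[str, int, str, str], set[str]] = {}
    for mid in sorted(cluster.member_ids):
        if mid == cluster.representative_id:
            continue
        blocks = align_to_representative(genomes[mid], rep, index=index)
        for sub in set(call_snvs(blocks)):
            key = (sub.rep_contig, sub.position, sub.ref, sub.alt)
            carriers.setdefault(key, set()).add(mid)
    records = [
        SNVRecord(
            species_id=cluster.species_id,
            rep_contig=contig,
            position=pos,
            ref=ref,
            alt=alt,
            carriers=sorted(who),
        )
        for (contig, pos, ref, alt), who in sorted(carriers.items())
        if len(who) >= min_carriers
    ]
    return records


def tag_specific_snvs(
    catalog: Sequence[SNVRecord],
    metadata: dict[str, tuple[str, str]],
    genomes_per_continent: dict[str, int] | None = None,
) -> tuple[list[SNVRecord], dict[str, float]]:
    """Flag continent/type-specific SNVs and compute per-continent
    normalized contributions.

    ``metadata`` maps genome_id -> (continent, genome_type); carriers with
    missing continent metadata are excluded from the continent-specificity
    determination. The contribution of continent c is the number of SNVs
    specific to c divided by the number of genomes from c
    (``genomes_per_continent``, defaulting to counts over ``metadata``).
    """
    if genomes_per_continent is None:
        genomes_per_continent = {}
        for cont, _ in metadata.values():
            if cont:
                genomes_per_continent[cont] = genomes_per_continent.get(cont, 0) + 1
    specific_counts: dict[str, int] = {}
    for rec in catalog:
        conts = {metadata[c][0] for c in rec.carriers if c in metadata and metadata[c][0]}
        types = {metadata[c][1] for c in rec.carriers if c in metadata}
        rec.continents = conts
        rec.genome_types = types
        rec.continent_specific = len(conts) == 1
        rec.type_specific = len(types) == 1
        if rec.continent_specific:
            cont = next(iter(conts))
            specific_counts[cont] = specific_counts.get(cont, 0) + 1
    contributions = {
        cont: specific_counts.get(cont, 0) / n
        for cont, n in sorted(genomes_per_continent.items())
        if n > 0
    }
    return list(catalog), contributions


def pairwise_snv_density(
    cluster: SpeciesCluster,
    genomes: dict[str, GenomeRecord],
    min_completeness: float = 90.0,
    min_genomes: int = 10,
    cap: int = 1000,
    denominator: str = "aligned",
) -> pd.DataFrame | None:
    """Pairwise SNV densities (SNVs per kb) between conspecific genomes.

    Only near-complete genomes (completeness >= ``min_completeness``) are
    used and the species must retain at least ``min_genomes`` of them;
    larger species are limited to the ``cap`` best-quality genomes by
    representative score. The density denominator is the representative-
    axis aligned length of the pair ("aligned", default) or the mean
    genome length ("genome").
    """
    eligible = [
        genomes[m]
        for m in cluster.member_ids
        if genomes[m].completeness >= min_completeness
    ]
    if len(eligible) < min_genomes:
        return None
    eligible = sorted(eligible, key=_rank_key)[:cap]
    rows = []
    for a, b in combinations(eligible, 2):
        index = AnchorIndex(b)
        blocks = align_to_representative(a, b, index=index)
        n_snv = len(call_snvs(blocks))
        aligned = aligned_rep_bases(blocks)
        denom = aligned if denominator == "aligned" else (a.length + b.length) / 2
        density = n_snv / (denom / 1000.0) if denom else float("nan")
        rows.append(
            {
                "genome_a": a.genome_id,
                "genome_b": b.genome_id,
                "n_snvs": n_snv,
                "aligned_bp": aligned,
                "density_per_kb": density,
                "type_pair": "-".join(sorted([a.genome_type, b.genome_type])),
                "continent_pair": "-".join(sorted([a.continent, b.continent])),
                "same_continent": a.continent == b.continent,
            }
        )
    return pd.DataFrame(rows)


def catalog_to_frame(catalog: Sequence[SNVRecord]) -> pd.DataFrame:
    rows = [
        {
            "species_id": r.species_id,
            "contig": r.rep_contig,
            "position": r.position,
            "ref": r.ref,
            "alt": r.alt,
            "n_support": len(r.carriers),
            "carriers": ",".join(r.carriers),
            "continents": ",".join(sorted(r.continents)),
            "genome_types": ",".join(sorted(r.genome_types)),
            "continent_specific": r.continent_specific,
            "type_specific": r.type_specific,
        }
        for r in catalog
    ]
    return pd.DataFrame(rows)
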