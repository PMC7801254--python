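"""MinHash genome sketching, Mash-style distance and fragment-based ANI/AF.

This is the distance kernel behind every clustering step. A sketch is the
bottom-s set of 64-bit hashes over canonical k-mers (k = 21, s = 1,000 by
default); the Mash distance d = -(1/k) ln(2j / (1 + j)) converts the
sketch-estimated Jaccard index j into a mutation-rate-scale distance, so
d = 0.001 corresponds to ~99.9 % nucleotide identity. ANI between two
genomes is estimated by cutting the query into fixed-length fragments,
anchoring each fragment on the target via shared k-mers (diagonal voting
over both strands) and scoring the anchored placement with a banded
alignment; ANI is the mean identity of mapped fragments and the alignment
fraction (AF) is the covered fraction of either genome, reported under a
configurable coverage mode ("larger" by default: the maximum of the two
directional covered fractions).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np

from .io import GenomeRecord

DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 1000
DEFAULT_HASH_SEED = 42  # fixed and recorded; all sketches in a run share it

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_ints(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mer integers (2-bit packed) and a validity mask.

    Windows containing any non-ACGT base are flagged invalid.
    """
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    valid_base = codes <= 3
    bad = np.concatenate([[0], np.cumsum(~valid_base)])
    window_valid = (bad[k:] - bad[:-k]) == 0
    c = np.where(valid_base, codes, 0).astype(np.uint64)
    windows = np.lib.stride_tricks.sliding_window_view(c, k)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    ints = windows @ powers
    return ints, window_valid


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical (strand-symmetric) k-mer integers of a sequence.

    The canonical form is the lexicographic minimum of a k-mer and its
    reverse complement, computed on the 2-bit integer encoding.
    """
    codes = _codes(seq)
    fwd, valid = _kmer_ints(codes, k)
    if fwd.size == 0:
        return fwd
    rc_codes = np.where(codes[::-1] <= 3, 3 - codes[::-1], 255).astype(np.uint8)
    rc, _ = _kmer_ints(rc_codes, k)
    canon = np.minimum(fwd, rc[::-1])
    return canon[valid]


def _splitmix64(x: np.ndarray, seed: int) -> np.ndarray:
    """Seeded 64-bit finalizer (splitmix64); vectorised, wraps mod 2**64."""
    z = x ^ np.uint64(seed)
    z = (z + np.uint64(0x9E3779B97F4A7C15))
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@dataclass
class SketchProfile:
    genome_id: str
    k: int
    sketch_size: int
    hashes: np.ndarray  # sorted ascending, <= sketch_size entries

    def __post_init__(self):
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)


def build_sketch(
    record: GenomeRecord,
    k: int = DEFAULT_K,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
    hash_seed: int = DEFAULT_HASH_SEED,
) -> SketchProfile:
    """Bottom-s MinHash sketch over canonical k-mers of all contigs."""
    if record.length < k:
        raise ValueError(
            f"genome {record.genome_id} shorter than k={k} ({record.length} bp)"
        )
    parts = [canonical_kmers(seq, k) for _, seq in record.contigs]
    kmers = np.unique(np.concatenate([p for p in parts if p.size] or [np.empty(0, np.uint64)]))
    hashes = np.unique(_splitmix64(kmers, hash_seed))
    hashes = np.sort(hashes)[:sketch_size]
    return SketchProfile(record.genome_id, k, sketch_size, hashes)


def sketch_jaccard(a: SketchProfile, b: SketchProfile) -> float:
    """Jaccard index estimated from the merged bottom-s sketch."""
    if a.k != b.k:
        raise ValueError(f"mismatched k: {a.k} vs {b.k}")
    if a.sketch_size != b.sketch_size:
        raise ValueError("mismatched sketch sizes")
    s = a.sketch_size
    merged = np.union1d(a.hashes, b.hashes)[:s]
    if merged.size == 0:
        return 0.0
    shared = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    n_shared = int(np.isin(merged, shared, assume_unique=True).sum())
    return n_shared / merged.size


def mash_distance(a: SketchProfile, b: SketchProfile) -> float:
    """d = -(1/k) ln(2j/(1+j)); d = 1 by convention when no hash is shared."""
    j = sketch_jaccard(a, b)
    if j <= 0.0:
        return 1.0
    if j >= 1.0:
        return 0.0
    d = -math.log(2.0 * j / (1.0 + j)) / a.k
    return min(d, 1.0)


# ---------------------------------------------------------------------------
# Fragment-based ANI / alignment fraction
# ---------------------------------------------------------------------------

ANCHOR_K = 15
_SEPARATOR = "N" * ANCHOR_K


@dataclass
class ANIResult:
    """ANI (% identity of mapped fragments) and alignment fraction.

    ``ani`` is None when no fragment maps (flagged by ``af == 0``).
    """

    ani: float | None
    af: float
    n_fragments_mapped: int
    query_coverage: float = 0.0
    target_coverage: float = 0.0


@dataclass
class FragmentIndex:
    """k-mer position index over a target genome (contigs concatenated with
    N spacers so anchors never span a contig boundary)."""

    genome_id: str
    sequence: str
    positions: dict = field(repr=False, default_factory=dict)

    @classmethod
    def build(cls, record: GenomeRecord, k: int = ANCHOR_K) -> "FragmentIndex":
        seq = _SEPARATOR.join(s for _, s in record.contigs)
        ints, valid = _kmer_ints(_codes(seq), k)
        index: dict[int, list[int]] = {}
        for pos in np.nonzero(valid)[0]:
            index.setdefault(int(ints[pos]), []).append(int(pos))
        return cls(record.genome_id, seq, index)


def _fragments(record: GenomeRecord, fragment_len: int, min_len: int = 100) -> list[str]:
    """Non-overlapping fragments covering every contig end to end.

    A short trailing piece is merged into the previous fragment so the
    fragments tile each contig exactly; contigs shorter than ``min_len``
    are skipped.
    """
    frags: list[str] = []
    for _, seq in record.contigs:
        if len(seq) < min_len:
            continue
        pieces = [seq[i : i + fragment_len] for i in range(0, len(seq), fragment_len)]
        if len(pieces) > 1 and len(pieces[-1]) < fragment_len // 2:
            tail = pieces.pop()
            pieces[-1] += tail
        frags.extend(pieces)
    return frags


def _vote_placement(frag: str, index: FragmentIndex, k: int, step: int, band: int = 64):
    """Best diagonal placement of a fragment on the indexed target.

    Returns (votes, strand, target_start_estimate) for the winning strand,
    breaking ties toward the leftmost target position.
    """
    best = (0, "+", 0)
    for strand, seq in (("+", frag), ("-", reverse_complement(frag))):
        ints, valid = _kmer_ints(_codes(seq), k)
        votes: Counter = Counter()
        for fpos in range(0, ints.size, step):
            if not valid[fpos]:
                continue
            for tpos in index.positions.get(int(ints[fpos]), ()):
                votes[(tpos - fpos) // band] += 1
        if not votes:
            continue
        # merge adjacent diagonal buckets, pick the heaviest, leftmost
        bucket, n = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))
        n += votes.get(bucket - 1, 0) + votes.get(bucket + 1, 0)
        if n > best[0]:
            best = (n, strand, bucket * band)
    return best


def ani_af(
    query: GenomeRecord,
    target: GenomeRecord,
    fragment_len: int = 1000,
    coverage_mode: str = "larger",
    min_identity: float = 0.8,
    min_anchor_votes: int = 2,
    index: FragmentIndex | None = None,
    anchor_step: int = 4,
) -> ANIResult:
    """Estimate ANI and alignment fraction between two genomes.

    The query is cut into non-overlapping ``fragment_len`` fragments, each
    anchored on the target by shared ``ANCHOR_K``-mers and scored with a
    banded infix alignment. ANI is the mean percent identity of mapped
    fragments; directional coverages are the mapped fraction of each
    genome, combined per ``coverage_mode`` ("larger", "smaller" or
    "query").
    """
    if coverage_mode not in ("larger", "smaller", "query"):
        raise ValueError(f"unknown coverage mode: {coverage_mode}")
    if index is None:
        index = FragmentIndex.build(target)
    tlen = len(index.sequence)
    frags = _fragments(query, fragment_len)
    qlen = sum(len(f) for f in frags)
    if qlen == 0:
        return ANIResult(None, 0.0, 0)

    identities: list[float] = []
    mapped_len = 0
    covered: list[tuple[int, int]] = []
    pad = max(50, fragment_len // 10)
    for frag in frags:
        votes, strand, t0 = _vote_placement(frag, index, ANCHOR_K, anchor_step)
        if votes < min_anchor_votes:
            continue
        lo = max(0, t0 - pad)
        hi = min(tlen, t0 + len(frag) + pad)
        window = index.sequence[lo:hi]
        q = frag if strand == "+" else reverse_complement(frag)
        aln = edlib.align(q, window, task="path", mode="HW")
        if aln["editDistance"] < 0 or not aln["cigar"]:
            continue
        n_match = n_cols = 0
        for count, op in _cigar_ops(aln["cigar"]):
            n_cols += count
            if op == "=":
                n_match += count
        ident = n_match / n_cols if n_cols else 0.0
        if ident < min_identity:
            continue
        identities.append(ident)
        mapped_len += len(frag)
        start, end = aln["locations"][0]
        covered.append((lo + start, lo + end + 1))

    if not identities:
        return ANIResult(None, 0.0, 0)
    qcov = min(1.0, mapped_len / qlen)
    tcov = min(1.0, _union_length(covered) / tlen) if tlen else 0.0
    af = {"larger": max(qcov, tcov), "smaller": min(qcov, tcov), "query": qcov}[coverage_mode]
    return ANIResult(
        ani=100.0 * float(np.mean(identities)),
        af=af,
        n_fragments_mapped=len(identities),
        query_coverage=qcov,
        target_coverage=tcov,
    )


def _cigar_ops(cigar: str):
    count = 0
    for ch in cigar:
        if ch.isdigit():
            count = count * 10 + int(ch)
        else:
            yield count, ch
            count = 0


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    end = -1
    for s, e in sorted(intervals):
        if s > end:
            total += e - s
            end = e
        elif e > end:
            total += e - end
            end = e
    return total
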