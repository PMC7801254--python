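"""Genome quality scoring, filtering, quality tiers and strain heterogeneity.

The admission rule for a genome collection is strict on all three axes:
completeness > 50 %, contamination < 5 % and quality score
QS = completeness - 5 x contamination > 50. Representative selection within
a species cluster additionally rewards assembly contiguity through an N50
term. The "high" quality tier follows the Genomic Standards Consortium
criteria for near-complete genomes with a full rRNA operon and at least 18
of the 20 standard tRNAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenomeRecord


@dataclass(frozen=True)
class QualityAssessment:
    qs: float
    passes_filter: bool
    gsc_tier: str  # "high" | "medium"
    rep_score: float


@dataclass(frozen=True)
class HeterogeneityResult:
    """Strain-heterogeneity estimate, or an insufficient-data flag when
    fewer than ``min_positions`` pileup positions qualify."""

    percent: float | None
    n_qualifying: int
    sufficient: bool


def quality_score(completeness: float, contamination: float) -> float:
    """QS = completeness - 5 x contamination (may be negative)."""
    if not (0 <= completeness <= 100):
        raise ValueError(f"completeness out of range [0,100]: {completeness}")
    if not (0 <= contamination <= 100):
        raise ValueError(f"contamination out of range [0,100]: {contamination}")
    return completeness - 5.0 * contamination


def passes_quality_filter(record: GenomeRecord) -> bool:
    """Strict filter: completeness > 50, contamination < 5 and QS > 50."""
    qs = quality_score(record.completeness, record.contamination)
    return record.completeness > 50.0 and record.contamination < 5.0 and qs > 50.0


def representative_score(
    completeness: float, contamination: float, n50: int, log_base: float = 10.0
) -> float:
    """Score = completeness - 5 x contamination + 0.5 x log(N50).

    Ranks conspecific genomes for representative selection. The log base is
    configurable (default 10, matching the magnitude convention of standard
    dereplication scoring).
    """
    if n50 < 1:
        raise ValueError(f"n50 must be >= 1, got {n50}")
    return quality_score(completeness, contamination) + 0.5 * math.log(n50, log_base)


def gsc_quality_tier(record: GenomeRecord) -> str:
    """"high" requires >90 % completeness, <5 % contamination, the 5S, 16S
    and 23S rRNA genes and at least 18 standard tRNAs; everything else that
    passed the admission filter is "medium"."""
    high = (
        record.completeness > 90.0
        and record.contamination < 5.0
        and record.n_5S >= 1
        and record.n_16S >= 1
        and record.n_23S >= 1
        and record.n_tRNA >= 18
    )
    return "high" if high else "medium"


def assess(record: GenomeRecord) -> QualityAssessment:
    return QualityAssessment(
        qs=quality_score(record.completeness, record.contamination),
        passes_filter=passes_quality_filter(record),
        gsc_tier=gsc_quality_tier(record),
        rep_score=representative_score(
            record.completeness, record.contamination, max(record.n50, 1)
        ),
    )


def strain_heterogeneity(
    pileup: pd.DataFrame,
    min_depth: int = 10,
    min_baseq: float = 30.0,
    min_positions: int = 100,
    minor_fraction_threshold: float = 0.2,
) -> HeterogeneityResult:
    """Fraction (%) of qualifying pileup positions that are polymorphic.

    ``pileup`` columns: ``position``, allele counts ``A C G T`` and mean
    base qualities ``baseq_A .. baseq_T``. Alleles whose mean base quality
    falls below ``min_baseq`` are discarded before the depth gate. A
    position qualifies when its retained depth is >= ``min_depth``; it is
    polymorphic when minor-allele count / depth >= ``minor_fraction_threshold``.
    At least ``min_positions`` qualifying positions are needed for an
    estimate, otherwise the result is flagged insufficient.

    This is an annotation-free simplification of coding-region
    nonsynonymous-substitution counting: no gene models are consulted and
    every genomic position is eligible.
    """
    alleles = ["A", "C", "G", "T"]
    if len(pileup) == 0:
        return HeterogeneityResult(percent=None, n_qualifying=0, sufficient=False)
    counts = pileup[alleles].to_numpy(dtype=float).copy()
    for j, a in enumerate(alleles):
        qcol = f"baseq_{a}"
        if qcol in pileup.columns:
            counts[pileup[qcol].to_numpy(dtype=float) < min_baseq, j] = 0.0
    depth = counts.sum(axis=1)
    qualifying = depth >= min_depth
    n_qual = int(qualifying.sum())
    if n_qual < min_positions:
        return HeterogeneityResult(percent=None, n_qualifying=n_qual, sufficient=False)
    cq = counts[qualifying]
    dq = depth[qualifying]
    minor = dq - cq.max(axis=1)
    polymorphic = (minor / dq) >= minor_fraction_threshold
    pct = 100.0 * float(np.count_nonzero(polymorphic)) / n_qual
    return HeterogeneityResult(percent=pct, n_qualifying=n_qual, sufficient=True)


def qc_report(records) -> pd.DataFrame:
    """Per-genome QC table, sorted by genome_id for deterministic output."""
    rows = []
    for r in sorted(records, key=lambda r: r.genome_id):
        a = assess(r)
        rows.append(
            {
                "genome_id": r.genome_id,
                "completeness": r.completeness,
                "contamination": r.contamination,
                "qs": a.qs,
                "passes_filter": a.passes_filter,
                "gsc_tier": a.gsc_tier,
                "rep_score": a.rep_score,
                "n50": r.n50,
                "length": r.length,
                "n_contigs": r.n_contigs,
            }
        )
    return pd.DataFrame(rows)
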