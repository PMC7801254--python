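"""Counts-only replay of published summary arithmetic.

Catalog papers report derived totals (merged collection sizes, species
counts split by domain, catalog-merge growth percentages) whose inputs are
printed per-category counts. These helpers recompute the derived numbers
from those printed inputs, so the arithmetic claims are testable without
the underlying multi-terabyte dataset.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .pangenome import merge_percent_increase

__all__ = [
    "merged_collection_total",
    "species_total",
    "merge_percent_increase",
]


def merged_collection_total(study_counts: Mapping[str, int] | Sequence[int]) -> int:
    """Total genomes in a merged collection = sum of per-study counts."""
    values = (
        list(study_counts.values())
        if isinstance(study_counts, Mapping)
        else list(study_counts)
    )
    if any(v < 0 for v in values):
        raise ValueError("study counts must be non-negative")
    return int(sum(values))


def species_total(n_bacterial: int, n_archaeal: int) -> int:
    """Total species = bacterial + archaeal cluster counts."""
    if n_bacterial < 0 or n_archaeal < 0:
        raise ValueError("species counts must be non-negative")
    return int(n_bacterial) + int(n_archaeal)
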