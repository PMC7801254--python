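"""Readers and writers for the formats the pipeline touches.

Genome assemblies travel as (optionally gzipped) FASTA, one file per genome;
per-genome metadata as a tab-delimited table with a fixed header; trees as
newick. All coordinates emitted anywhere in the package are 1-based, fully
closed, on the representative genome's forward strand.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
import skbio

METADATA_COLUMNS = [
    "genome_id",
    "study_set",
    "genome_type",
    "sample_id",
    "country",
    "continent",
    "completeness",
    "contamination",
    "n_5S",
    "n_16S",
    "n_23S",
    "n_tRNA",
]

GENOME_TYPES = ("isolate", "MAG")

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")


@dataclass
class GenomeRecord:
    """One assembly plus its metadata and quality fields.

    ``contigs`` holds ``(contig_id, sequence)`` pairs with uppercase DNA.
    ``completeness`` and ``contamination`` are percentages as estimated
    upstream (e.g. by CheckM); they are inputs here, never recomputed.
    """

    genome_id: str
    contigs: list[tuple[str, str]] = field(default_factory=list)
    study_set: str = ""
    genome_type: str = "MAG"
    sample_id: str = ""
    country: str = ""
    continent: str = ""
    completeness: float = 100.0
    contamination: float = 0.0
    n_5S: int = 0
    n_16S: int = 0
    n_23S: int = 0
    n_tRNA: int = 0

    @property
    def length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def n50(self) -> int:
        """Minimum contig size such that contigs at least that long cover
        half the assembly."""
        if not self.contigs:
            return 0
        lengths = sorted((len(s) for _, s in self.contigs), reverse=True)
        half = sum(lengths) / 2
        acc = 0
        for ln in lengths:
            acc += ln
            if acc >= half:
                return ln
        return lengths[-1]

    def sequence(self) -> str:
        """All contigs concatenated (no separator); convenience for tests."""
        return "".join(s for _, s in self.contigs)


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) FASTA into ``(id, uppercase sequence)`` pairs.

    Raises ``ValueError`` on characters outside the IUPAC DNA alphabet.
    """
    path = Path(path)
    contigs: list[tuple[str, str]] = []
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            bad = set(seq) - _IUPAC_DNA
            if bad:
                raise ValueError(
                    f"{path}: contig {rec.id} contains non-IUPAC characters: "
                    f"{sorted(bad)}"
                )
            contigs.append((rec.id, seq))
    return contigs


def write_fasta(path: str | Path, contigs: Iterable[tuple[str, str]], width: int = 80) -> None:
    """Write contigs as FASTA with ``width``-column wrapped sequence lines."""
    path = Path(path)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as out:
        for cid, seq in contigs:
            out.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def read_metadata(metadata_tsv: str | Path) -> pd.DataFrame:
    """Read the per-genome metadata table and validate its header."""
    df = pd.read_csv(metadata_tsv, sep="\t", dtype={"genome_id": str, "sample_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    dup = df["genome_id"][df["genome_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate genome_id in metadata: {sorted(set(dup))}")
    return df


def read_genome_collection(
    fasta_dir: str | Path,
    metadata_tsv: str | Path,
    metadata_only: bool = False,
) -> list[GenomeRecord]:
    """Load a genome collection from a FASTA directory plus metadata TSV.

    Each metadata row must have a matching ``<genome_id>.fa``,
    ``<genome_id>.fasta`` or gzipped variant in ``fasta_dir``. With
    ``metadata_only`` the sequences are skipped and records carry metadata
    only (used for counts-only replays of published per-study tallies).
    """
    fasta_dir = Path(fasta_dir)
    meta = read_metadata(metadata_tsv)
    records: list[GenomeRecord] = []
    for row in meta.itertuples(index=False):
        rec = GenomeRecord(
            genome_id=row.genome_id,
            study_set=str(row.study_set),
            genome_type=str(row.genome_type),
            sample_id=str(row.sample_id),
            country=str(row.country),
            continent=str(row.continent),
            completeness=float(row.completeness),
            contamination=float(row.contamination),
            n_5S=int(row.n_5S),
            n_16S=int(row.n_16S),
            n_23S=int(row.n_23S),
            n_tRNA=int(row.n_tRNA),
        )
        if not metadata_only:
            path = None
            for suffix in (".fa", ".fasta", ".fa.gz", ".fasta.gz"):
                cand = fasta_dir / f"{row.genome_id}{suffix}"
                if cand.exists():
                    path = cand
                    break
            if path is None:
                raise FileNotFoundError(
                    f"no FASTA found for genome_id {row.genome_id!r} in {fasta_dir}"
                )
            rec.contigs = read_fasta(path)
        records.append(rec)
    return records


def collection_size_by_study(records: Sequence[GenomeRecord]) -> pd.Series:
    """Per-study genome counts; their sum is the merged-collection size."""
    return pd.Series([r.study_set for r in records]).value_counts().sort_index()


def write_metadata(path: str | Path, records: Sequence[GenomeRecord]) -> None:
    rows = [
        {
            "genome_id": r.genome_id,
            "study_set": r.study_set,
            "genome_type": r.genome_type,
            "sample_id": r.sample_id,
            "country": r.country,
            "continent": r.continent,
            "completeness": r.completeness,
            "contamination": r.contamination,
            "n_5S": r.n_5S,
            "n_16S": r.n_16S,
            "n_23S": r.n_23S,
            "n_tRNA": r.n_tRNA,
        }
        for r in sorted(records, key=lambda r: r.genome_id)
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_newick(path_or_str: str | Path) -> skbio.TreeNode:
    """Parse a newick tree with branch lengths and leaf labels.

    Accepts a path or a newick string. Unbalanced parentheses or other
    syntax errors surface as ``ValueError`` with the parser's position
    information.
    """
    src = str(path_or_str)
    try:
        is_file = Path(src).exists()
    except OSError:  # e.g. a long newick string is not a valid path
        is_file = False
    try:
        if is_file:
            tree = skbio.TreeNode.read(src, format="newick")
        else:
            tree = skbio.TreeNode.read([src], format="newick")
    except Exception as exc:  # skbio raises NewickFormatError
        raise ValueError(f"newick parse error: {exc}") from exc
    return tree


def write_newick(path: str | Path, tree: skbio.TreeNode) -> None:
    tree.write(str(path), format="newick")


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as out:
        json.dump(obj, out, indent=1, sort_keys=True)
        out.write("\n")


def read_json(path: str | Path):
    with open(path) as handle:
        return json.load(handle)
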