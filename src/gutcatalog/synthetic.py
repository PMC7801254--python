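"""Synthetic genome collections with planted ground truth.

The generator emulates the statistical structure the catalog pipeline
assumes: multiple species whose ancestors diverge well past the 95 % ANI
species boundary, conspecific genomes differing by point substitutions
drawn from a species-level pool of segregating sites (so alternate alleles
recur in several carriers), assembly incompleteness applied as whole-contig
deletions, occasional cross-species contaminant contigs, isolate/MAG
labels, and sample/continent metadata. Every planted feature is recorded
in a machine-readable truth object so recovery can be scored exactly.

Species ancestors are derived from one root sequence mutated independently
at ``interspecies_divergence`` per species; two ancestors therefore differ
at ~2d(1-2d/3) of sites, far below the species boundary for the required
d > 0.05. Conspecific substitutions are substitutions only by default;
short indels can be switched on for variant-exclusion testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import GenomeRecord, write_fasta, write_json, write_metadata
from .pangenome import ProteinSeq

_BASES = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

DEFAULT_CONTINENTS = {
    "Africa": 0.05,
    "Asia": 0.25,
    "Europe": 0.30,
    "North America": 0.25,
    "South America": 0.05,
    "Oceania": 0.10,
}

_COUNTRY = {
    "Africa": "Tanzania",
    "Asia": "China",
    "Europe": "Denmark",
    "North America": "United States",
    "South America": "Peru",
    "Oceania": "Fiji",
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic collection; defaults are the desk-scale study
    conditions the pipeline is exercised under."""

    n_species: int = 5
    genomes_per_species: tuple[int, int] = (12, 12)  # inclusive min/max
    genome_length: int = 100_000
    interspecies_divergence: float = 0.10
    intraspecies_snv_rate: float = 0.002  # substitutions per bp per genome
    site_carrier_prob: float = 0.3  # per-genome chance of carrying a site's alt
    n_core_genes: int = 40
    n_accessory_genes: int = 40
    accessory_presence_prob: float = 0.08
    within_family_divergence: float = 0.015
    protein_length: tuple[int, int] = (80, 200)
    incompleteness_range: tuple[float, float] = (0.0, 0.10)
    contamination_prob: float = 0.10
    contamination_fraction: float = 0.03
    isolate_fraction: float = 0.2
    contigs_per_genome: tuple[int, int] = (4, 10)
    continents: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CONTINENTS))
    n_samples: int | None = None
    indel_rate: float = 0.0  # per bp per genome; lengths 1..indel_max_len
    indel_max_len: int = 3
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "intraspecies_snv_rate": self.intraspecies_snv_rate,
            "site_carrier_prob": self.site_carrier_prob,
            "accessory_presence_prob": self.accessory_presence_prob,
            "within_family_divergence": self.within_family_divergence,
            "contamination_prob": self.contamination_prob,
            "contamination_fraction": self.contamination_fraction,
            "isolate_fraction": self.isolate_fraction,
            "indel_rate": self.indel_rate,
        }
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.interspecies_divergence <= 0.05:
            raise ValueError(
                "interspecies_divergence must exceed 0.05: smaller values can "
                "leave species pairs above 95% ANI, violating the species "
                "separability assumption"
            )
        lo, hi = self.incompleteness_range
        if not (0.0 <= lo <= hi < 0.5):
            raise ValueError("incompleteness_range must satisfy 0 <= lo <= hi < 0.5")
        if self.genomes_per_species[0] < 1 or self.n_species < 1:
            raise ValueError("need at least one species and one genome per species")
        if abs(sum(self.continents.values()) - 1.0) > 1e-9:
            raise ValueError("continent weights must sum to 1")


@dataclass
class SyntheticTruth:
    """Planted ground truth of one generated collection."""

    genome_species: dict[str, str] = field(default_factory=dict)
    # species -> list of sites; each site: position (0-based, ancestral),
    # ref, alt, carriers (alt applied), surviving_carriers (alt retained
    # after deletion)
    snv_sites: dict[str, list[dict]] = field(default_factory=dict)
    # genome -> contig layout on the ancestral coordinate system
    contig_layout: dict[str, list[dict]] = field(default_factory=dict)
    gene_presence: dict[str, list[str]] = field(default_factory=dict)
    deleted_fraction: dict[str, float] = field(default_factory=dict)
    contamination_fraction: dict[str, float] = field(default_factory=dict)
    indels: dict[str, list[dict]] = field(default_factory=dict)
    ancestors: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "genome_species": self.genome_species,
            "snv_sites": self.snv_sites,
            "contig_layout": self.contig_layout,
            "gene_presence": self.gene_presence,
            "deleted_fraction": self.deleted_fraction,
            "contamination_fraction": self.contamination_fraction,
            "indels": self.indels,
            "ancestors": self.ancestors,
        }


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Substitute each given position with a uniformly different base."""
    out = seq.copy()
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return out


def generate_collection(
    config: SimulationConfig,
) -> tuple[list[GenomeRecord], SyntheticTruth]:
    """Generate genomes plus truth. Deterministic for a fixed config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = SyntheticTruth()
    L = config.genome_length

    root = _random_seq(rng, L)
    species_ids = [f"sp{s + 1:02d}" for s in range(config.n_species)]
    ancestors: dict[str, np.ndarray] = {}
    for sp in species_ids:
        n_mut = round(config.interspecies_divergence * L)
        pos = rng.choice(L, size=n_mut, replace=False)
        ancestors[sp] = _mutate(rng, root, pos)
        truth.ancestors[sp] = "".join(ancestors[sp])

    # species-level segregating sites: expected per-genome substitution
    # count = n_sites * carrier_prob = rate * L
    sites: dict[str, list[dict]] = {}
    for sp in species_ids:
        n_sites = round(config.intraspecies_snv_rate * L / config.site_carrier_prob)
        pos = np.sort(rng.choice(L, size=min(n_sites, L), replace=False))
        sp_sites = []
        for p in pos:
            ref = ancestors[sp][p]
            alt = [b for b in "ACGT" if b != ref][rng.integers(0, 3)]
            sp_sites.append(
                {"position": int(p), "ref": str(ref), "alt": alt,
                 "carriers": [], "surviving_carriers": []}
            )
        sites[sp] = sp_sites

    # sample / continent assignment
    n_genomes_per_sp = [
        int(rng.integers(config.genomes_per_species[0], config.genomes_per_species[1] + 1))
        for _ in species_ids
    ]
    total = sum(n_genomes_per_sp)
    n_samples = config.n_samples or max(1, (2 * total) // 3)
    cont_names = sorted(config.continents)
    weights = np.array([config.continents[c] for c in cont_names])
    sample_continent = {
        f"sample_{i + 1:04d}": cont_names[rng.choice(len(cont_names), p=weights)]
        for i in range(n_samples)
    }
    sample_ids = sorted(sample_continent)

    records: list[GenomeRecord] = []
    counter = 0
    for sp, n_genomes in zip(species_ids, n_genomes_per_sp):
        for _ in range(n_genomes):
            counter += 1
            gid = f"genome_{counter:04d}"
            truth.genome_species[gid] = sp
            seq = ancestors[sp].copy()

            applied: list[int] = []
            for si, site in enumerate(sites[sp]):
                if rng.random() < config.site_carrier_prob:
                    seq[site["position"]] = site["alt"]
                    site["carriers"].append(gid)
                    applied.append(si)

            anc_of = np.arange(L, dtype=np.int64)  # mutated idx -> ancestral
            if config.indel_rate > 0:
                n_ind = rng.poisson(config.indel_rate * L)
                for _ in range(n_ind):
                    p = int(rng.integers(0, len(seq)))
                    ln = int(rng.integers(1, config.indel_max_len + 1))
                    if rng.random() < 0.5 and len(seq) > ln + 1:
                        truth.indels.setdefault(gid, []).append(
                            {"kind": "del", "anc_position": int(anc_of[p]), "length": ln}
                        )
                        seq = np.delete(seq, np.s_[p : p + ln])
                        anc_of = np.delete(anc_of, np.s_[p : p + ln])
                    else:
                        ins = _random_seq(rng, ln)
                        truth.indels.setdefault(gid, []).append(
                            {"kind": "ins", "anc_position": int(anc_of[p]), "length": ln}
                        )
                        seq = np.insert(seq, p, ins)
                        anc_of = np.insert(anc_of, p, np.full(ln, -1))

            # incompleteness: one contiguous deleted block whose edges fall
            # on contig boundaries, then fragmentation of what remains
            full_len = len(seq)
            target_del = int(round(rng.uniform(*config.incompleteness_range) * full_len))
            junction = None
            if target_del > 0:
                s0 = int(rng.integers(0, full_len - target_del))
                seq = np.delete(seq, np.s_[s0 : s0 + target_del])
                anc_of = np.delete(anc_of, np.s_[s0 : s0 + target_del])
                if 0 < s0 < len(seq):
                    junction = s0  # becomes a contig boundary below

            n_contigs = int(rng.integers(*config.contigs_per_genome, endpoint=True))
            n_contigs = max(1, min(n_contigs, len(seq) // 1000))
            cut_set: set[int] = {junction} if junction is not None else set()
            candidates = np.setdiff1d(np.arange(1, len(seq)), list(cut_set))
            extra = max(0, n_contigs - 1 - len(cut_set))
            if extra:
                cut_set.update(
                    int(c) for c in rng.choice(candidates, size=extra, replace=False)
                )
            cuts = np.sort(np.array(sorted(cut_set), dtype=int)) if cut_set else np.array([], dtype=int)
            bounds = np.concatenate([[0], cuts, [len(seq)]])
            n_contigs = len(bounds) - 1

            contigs: list[tuple[str, str]] = []
            layout = []
            keep_anc: list[np.ndarray] = []
            for order in range(n_contigs):
                a, b = int(bounds[order]), int(bounds[order + 1])
                cid = f"{gid}_c{order + 1}"
                contigs.append((cid, "".join(seq[a:b])))
                keep_anc.append(anc_of[a:b])
                layout.append(
                    {"contig_id": cid, "anc_start": int(anc_of[a]) if anc_of[a] >= 0 else -1,
                     "anc_end": int(anc_of[b - 1]) + 1 if anc_of[b - 1] >= 0 else -1}
                )
            surviving = set(np.concatenate(keep_anc).tolist()) if keep_anc else set()
            for si in applied:
                site = sites[sp][si]
                if site["position"] in surviving:
                    site["surviving_carriers"].append(gid)

            native_len = sum(len(s) for _, s in contigs)
            deleted_fraction = target_del / full_len

            contam_fraction = 0.0
            if rng.random() < config.contamination_prob and config.n_species > 1:
                donor = species_ids[
                    (species_ids.index(sp) + 1 + int(rng.integers(0, config.n_species - 1)))
                    % config.n_species
                ]
                clen = max(1000, int(config.contamination_fraction * L))
                start = int(rng.integers(0, L - clen))
                contigs.append(
                    (f"{gid}_contam", "".join(ancestors[donor][start : start + clen]))
                )
                contam_fraction = clen / (native_len + clen)

            is_isolate = rng.random() < config.isolate_fraction
            sample = sample_ids[int(rng.integers(0, n_samples))]
            continent = sample_continent[sample]
            completeness = round(100.0 * (1.0 - deleted_fraction), 2)
            contamination = round(100.0 * contam_fraction, 2)

            rec = GenomeRecord(
                genome_id=gid,
                contigs=contigs,
                study_set="synthetic",
                genome_type="isolate" if is_isolate else "MAG",
                sample_id=sample,
                country=_COUNTRY.get(continent, "unknown"),
                continent=continent,
                completeness=completeness,
                contamination=contamination,
                n_5S=1 if is_isolate else int(rng.random() < 0.4),
                n_16S=1 if is_isolate else int(rng.random() < 0.4),
                n_23S=1 if is_isolate else int(rng.random() < 0.4),
                n_tRNA=20 if is_isolate else int(rng.integers(10, 21)),
            )
            records.append(rec)
            truth.contig_layout[gid] = layout
            truth.deleted_fraction[gid] = deleted_fraction
            truth.contamination_fraction[gid] = contam_fraction

            families = [f"{sp}_core{i + 1:03d}" for i in range(config.n_core_genes)]
            families += [
                f"{sp}_acc{i + 1:03d}"
                for i in range(config.n_accessory_genes)
                if rng.random() < config.accessory_presence_prob
            ]
            truth.gene_presence[gid] = families

    truth.snv_sites = sites
    return records, truth


def generate_protein_set(
    config: SimulationConfig, truth: SyntheticTruth
) -> list[ProteinSeq]:
    """Amino-acid sequences for every (genome, gene family) in the truth.

    Each family has a random ancestral protein; members diverge from it at
    ``within_family_divergence`` per residue, so within-family identity is
    controlled while unrelated families share only chance identity
    (well under 50 %).
    """
    rng = np.random.default_rng(config.seed + 10_000)
    families = sorted({f for fams in truth.gene_presence.values() for f in fams})
    ancestral: dict[str, np.ndarray] = {}
    for fam in families:
        ln = int(rng.integers(*config.protein_length, endpoint=True))
        ancestral[fam] = _AA[rng.integers(0, 20, size=ln)]
    out: list[ProteinSeq] = []
    for gid in sorted(truth.gene_presence):
        sp = truth.genome_species[gid]
        for fam in sorted(truth.gene_presence[gid]):
            seq = ancestral[fam].copy()
            n_mut = rng.binomial(len(seq), config.within_family_divergence)
            if n_mut:
                pos = rng.choice(len(seq), size=n_mut, replace=False)
                for p in pos:
                    choices = _AA[_AA != seq[p]]
                    seq[p] = choices[rng.integers(0, len(choices))]
            out.append(ProteinSeq(f"{gid}|{fam}", gid, sp, "".join(seq)))
    return out


def generate_pileup(
    n_positions: int,
    depth_distribution: tuple = ("poisson", 30),
    polymorphic_fraction: float = 0.0,
    baseq_model: tuple = ("normal", 35.0, 2.0),
    seed: int = 0,
):
    """Per-position allele-count table plus the planted polymorphic set.

    ``depth_distribution``: ("poisson", mean) or ("fixed", depth);
    ``baseq_model``: ("normal", mean, sd) or ("fixed", q). Polymorphic
    positions carry a minor allele at 25-50 % frequency. Returns
    ``(DataFrame, polymorphic_positions)``.
    """
    import pandas as pd

    if not (0.0 <= polymorphic_fraction <= 1.0):
        raise ValueError("polymorphic_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    kind = depth_distribution[0]
    if kind == "poisson":
        depth = rng.poisson(depth_distribution[1], size=n_positions)
    elif kind == "fixed":
        depth = np.full(n_positions, int(depth_distribution[1]))
    else:
        raise ValueError(f"unknown depth distribution {kind!r}")
    is_poly = rng.random(n_positions) < polymorphic_fraction
    rows = []
    truth_positions = []
    for i in range(n_positions):
        counts = {b: 0 for b in "ACGT"}
        major, minor = rng.choice(4, size=2, replace=False)
        d = int(depth[i])
        if is_poly[i] and d > 0:
            mf = rng.uniform(0.25, 0.5)
            n_minor = max(1, int(round(mf * d)))
            counts[_BASES[major]] = d - n_minor
            counts[_BASES[minor]] = n_minor
            truth_positions.append(i + 1)
        else:
            counts[_BASES[major]] = d
        if baseq_model[0] == "normal":
            qs = rng.normal(baseq_model[1], baseq_model[2], size=4).round(1)
        elif baseq_model[0] == "fixed":
            qs = np.full(4, float(baseq_model[1]))
        else:
            raise ValueError(f"unknown baseq model {baseq_model[0]!r}")
        row = {"position": i + 1}
        row.update({b: counts[b] for b in "ACGT"})
        row.update({f"baseq_{b}": float(q) for b, q in zip("ACGT", qs)})
        rows.append(row)
    return pd.DataFrame(rows), truth_positions


def write_collection(
    outdir: str | Path,
    records: list[GenomeRecord],
    truth: SyntheticTruth,
    proteins: list[ProteinSeq] | None = None,
) -> None:
    """Write genomes/, metadata.tsv, truth.json (and proteins.faa)."""
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    for rec in sorted(records, key=lambda r: r.genome_id):
        write_fasta(outdir / "genomes" / f"{rec.genome_id}.fa", rec.contigs)
    write_metadata(outdir / "metadata.tsv", records)
    write_json(outdir / "truth.json", truth.to_json())
    if proteins is not None:
        write_fasta(
            outdir / "proteins.faa",
            [(p.seq_id, p.sequence) for p in proteins],
        )
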