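"""End-to-end orchestration: simulate -> qc -> cluster -> dereplicate ->
pan-genome -> SNV -> reports, with a run manifest.

Every stage is a pure function of the working directory contents plus the
seed; the manifest records the resolved configuration, per-stage timings
and record counts, and SHA-256 checksums of every output file, so a
re-run with identical inputs can be verified byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diversity, qc, snv
from .cluster import (
    SpeciesCluster,
    assign_cultured_status,
    cluster_species,
    dereplicate_conspecific,
    intraspecies_dendrogram,
    membership_table,
)
from .io import (
    GenomeRecord,
    read_genome_collection,
    write_json,
)
from .pangenome import ProteinSeq, build_pangenome, normalized_pangenome_size
from .synthetic import (
    SimulationConfig,
    generate_collection,
    generate_protein_set,
    write_collection,
)


@dataclass
class ClusteringParams:
    primary_distance: float = 0.10
    ani_threshold: float = 95.0
    af_threshold: float = 0.30
    chunk_size: int | None = None
    derep_mash_threshold: float = 0.001
    dendrogram_cutoffs: tuple[float, float] = (0.03, 0.01)
    fragment_len: int = 1000


@dataclass
class PanGenomeParams:
    identity: float = 0.90
    coverage: float = 0.8
    core_threshold: float = 0.90
    rare_threshold: float = 0.10


@dataclass
class SNVParams:
    min_members: int = 3
    min_carriers: int = 2
    density: bool = False
    density_min_completeness: float = 90.0
    density_min_genomes: int = 10
    density_cap: int = 1000


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    pangenome: PanGenomeParams = field(default_factory=PanGenomeParams)
    snv: SNVParams = field(default_factory=SNVParams)
    rarefaction_reps: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        cfg = cls()
        if "simulation" in raw:
            cfg.simulation = SimulationConfig(**_tupled(raw["simulation"]))
        if "clustering" in raw:
            cfg.clustering = ClusteringParams(**_tupled(raw["clustering"]))
        if "pangenome" in raw:
            cfg.pangenome = PanGenomeParams(**_tupled(raw["pangenome"]))
        if "snv" in raw:
            cfg.snv = SNVParams(**_tupled(raw["snv"]))
        cfg.rarefaction_reps = raw.get("rarefaction_reps", cfg.rarefaction_reps)
        cfg.seed = raw.get("seed", cfg.seed)
        cfg.simulation.seed = cfg.simulation.seed or cfg.seed
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


@dataclass
class CatalogTables:
    species: pd.DataFrame
    genomes: pd.DataFrame
    snvs: pd.DataFrame
    pangenomes: pd.DataFrame


@dataclass
class RunManifest:
    config: dict
    seed: int
    stage_seconds: dict[str, float] = field(default_factory=dict)
    record_counts: dict[str, int] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


# ---------------------------------------------------------------------------
# stages (each self-contained over the working directory)
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, workdir: Path):
    records, truth = generate_collection(config.simulation)
    proteins = generate_protein_set(config.simulation, truth)
    write_collection(workdir, records, truth, proteins)
    return records, truth, proteins


def load_workdir(workdir: Path) -> list[GenomeRecord]:
    return read_genome_collection(workdir / "genomes", workdir / "metadata.tsv")


def load_proteins(workdir: Path) -> list[ProteinSeq]:
    """Protein FASTA back as ProteinSeq; headers are genome_id|family."""
    out = []
    for seq_id, seq in read_protein_fasta(workdir / "proteins.faa"):
        genome_id = seq_id.split("|", 1)[0]
        out.append(ProteinSeq(seq_id, genome_id, "", seq))
    return out


def read_protein_fasta(path: Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def stage_qc(workdir: Path) -> pd.DataFrame:
    records = load_workdir(workdir)
    report = qc.qc_report(records)
    report.to_csv(workdir / "qc_report.tsv", sep="\t", index=False)
    return report


def stage_cluster(
    config: PipelineConfig, workdir: Path
) -> tuple[list[SpeciesCluster], pd.DataFrame]:
    records = load_workdir(workdir)
    passing = [r for r in records if qc.passes_quality_filter(r)]
    by_id = {r.genome_id: r for r in records}
    p = config.clustering
    cache: dict = {}
    clusters = cluster_species(
        passing,
        primary_distance=p.primary_distance,
        ani_threshold=p.ani_threshold,
        af_threshold=p.af_threshold,
        chunk_size=p.chunk_size,
        seed=config.seed,
        fragment_len=p.fragment_len,
        _sketch_cache=cache,
    )
    sample_continent = {r.sample_id: r.continent for r in records if r.sample_id}
    rows = []
    for cl in clusters:
        cl.nonredundant_ids = dereplicate_conspecific(
            cl, by_id, mash_threshold=p.derep_mash_threshold, _sketch_cache=cache
        )
        cl.cultured_status = assign_cultured_status(cl, by_id)
        counts = intraspecies_dendrogram(
            cl, by_id, cutoffs=p.dendrogram_cutoffs, _sketch_cache=cache
        )
        samples_with = {by_id[m].sample_id for m in cl.member_ids if by_id[m].sample_id}
        geo = diversity.geographic_diversity(
            cl.species_id, samples_with, sample_continent
        )
        row = {
            "species_id": cl.species_id,
            "representative_id": cl.representative_id,
            "n_members": len(cl.member_ids),
            "n_nonredundant": len(cl.nonredundant_ids),
            "cultured_status": cl.cultured_status,
            "geographic_diversity": geo.shannon_index,
        }
        for cutoff, n in counts.items():
            row[f"n_subclusters_{cutoff:g}"] = n
        rows.append(row)
    species_table = pd.DataFrame(rows)
    species_table.to_csv(workdir / "species_table.tsv", sep="\t", index=False)
    membership_table(clusters).to_csv(
        workdir / "species_clusters.tsv", sep="\t", index=False
    )
    return clusters, species_table


def _load_clusters(workdir: Path) -> list[SpeciesCluster]:
    mem = pd.read_csv(workdir / "species_clusters.tsv", sep="\t")
    spec = pd.read_csv(workdir / "species_table.tsv", sep="\t")
    reps = dict(zip(spec["species_id"], spec["representative_id"]))
    clusters = []
    for sid, grp in mem.groupby("species_id"):
        clusters.append(
            SpeciesCluster(
                species_id=sid,
                representative_id=reps[sid],
                member_ids=sorted(grp["genome_id"]),
            )
        )
    return sorted(clusters, key=lambda c: c.species_id)


def stage_pangenome(config: PipelineConfig, workdir: Path) -> pd.DataFrame:
    clusters = _load_clusters(workdir)
    proteins = load_proteins(workdir)
    species_of = {m: cl.species_id for cl in clusters for m in cl.member_ids}
    for p in proteins:
        p.species_id = species_of.get(p.genome_id, "")
    pg_params = config.pangenome
    rows = []
    pg_dir = workdir / "pangenome"
    pg_dir.mkdir(exist_ok=True)
    for cl in clusters:
        member_prot: dict[str, list[ProteinSeq]] = {m: [] for m in cl.member_ids}
        for p in proteins:
            if p.genome_id in member_prot:
                member_prot[p.genome_id].append(p)
        pg = build_pangenome(
            cl.species_id,
            member_prot,
            identity=pg_params.identity,
            coverage=pg_params.coverage,
        )
        if pg is None:
            continue
        rep_genes = len(member_prot.get(cl.representative_id, []))
        counts = pg.class_counts()
        pg.presence.astype(int).to_csv(
            pg_dir / f"{cl.species_id}.presence.tsv", sep="\t"
        )
        rows.append(
            {
                "species_id": cl.species_id,
                "n_gene_clusters": pg.n_clusters,
                "n_core": int(counts.get("core", 0)),
                "n_intermediate": int(counts.get("intermediate", 0)),
                "n_rare": int(counts.get("rare", 0)),
                "normalized_size": (
                    normalized_pangenome_size(pg, rep_genes) if rep_genes else float("nan")
                ),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(workdir / "pangenome_summary.tsv", sep="\t", index=False)
    return summary


def stage_snv(config: PipelineConfig, workdir: Path) -> pd.DataFrame:
    clusters = _load_clusters(workdir)
    records = load_workdir(workdir)
    by_id = {r.genome_id: r for r in records}
    meta = {r.genome_id: (r.continent, r.genome_type) for r in records}
    frames = []
    contributions_rows = []
    for cl in clusters:
        catalog = snv.build_species_snv_catalog(
            cl, by_id, min_members=config.snv.min_members,
            min_carriers=config.snv.min_carriers,
        )
        if catalog is None:
            continue
        catalog, contrib = snv.tag_specific_snvs(
            catalog,
            {m: meta[m] for m in cl.member_ids},
        )
        frames.append(snv.catalog_to_frame(catalog))
        for cont, value in contrib.items():
            contributions_rows.append(
                {"species_id": cl.species_id, "continent": cont,
                 "snvs_per_genome": value}
            )
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["species_id", "contig", "position", "ref", "alt", "n_support",
                     "carriers", "continents", "genome_types",
                     "continent_specific", "type_specific"]
        )
    )
    table.to_csv(workdir / "snv_catalog.tsv", sep="\t", index=False)
    pd.DataFrame(contributions_rows).to_csv(
        workdir / "snv_continent_contributions.tsv", sep="\t", index=False
    )
    if config.snv.density:
        dens_frames = []
        for cl in clusters:
            df = snv.pairwise_snv_density(
                cl, by_id,
                min_completeness=config.snv.density_min_completeness,
                min_genomes=config.snv.density_min_genomes,
                cap=config.snv.density_cap,
            )
            if df is not None:
                df.insert(0, "species_id", cl.species_id)
                dens_frames.append(df)
        if dens_frames:
            pd.concat(dens_frames, ignore_index=True).to_csv(
                workdir / "snv_density.tsv", sep="\t", index=False
            )
    return table


def stage_report(config: PipelineConfig, workdir: Path) -> pd.DataFrame:
    records = load_workdir(workdir)
    by_id = {r.genome_id: r for r in records}
    clusters = _load_clusters(workdir)
    cache: dict = {}
    labels = []
    for cl in clusters:
        nonredundant = dereplicate_conspecific(
            cl, by_id, mash_threshold=config.clustering.derep_mash_threshold,
            _sketch_cache=cache,
        )
        labels.extend([cl.species_id] * len(nonredundant))
    depths = range(1, len(labels) + 1)
    rows = []
    for exclude in (False, True):
        curve = diversity.rarefaction_curve(
            labels, n_reps=config.rarefaction_reps, seed=config.seed,
            exclude_singletons=exclude,
        )
        rows.extend(
            {"depth": d, "expected_species": v,
             "exclude_singletons": exclude}
            for d, v in zip(depths, curve)
        )
    table = pd.DataFrame(rows)
    table.to_csv(workdir / "rarefaction.tsv", sep="\t", index=False)
    return table


def run_pipeline(config: PipelineConfig, workdir: str | Path) -> tuple[CatalogTables, RunManifest]:
    """Execute every stage in order; abort with the stage name on failure."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    stages = [
        ("simulate", lambda: stage_simulate(config, workdir)),
        ("qc", lambda: stage_qc(workdir)),
        ("cluster", lambda: stage_cluster(config, workdir)),
        ("pangenome", lambda: stage_pangenome(config, workdir)),
        ("snv", lambda: stage_snv(config, workdir)),
        ("report", lambda: stage_report(config, workdir)),
    ]
    results = {}
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            results[name] = fn()
        except Exception as exc:
            raise StageError(name, str(exc)) from exc
        manifest.stage_seconds[name] = round(time.perf_counter() - t0, 3)

    clusters, species_table = results["cluster"]
    manifest.record_counts = {
        "genomes": len(results["simulate"][0]),
        "genomes_passing_qc": int(results["qc"]["passes_filter"].sum()),
        "species": len(clusters),
        "snvs": len(results["snv"]),
    }
    for path in sorted(workdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.checksums[str(path.relative_to(workdir))] = _sha256(path)
    write_json(workdir / "manifest.json", manifest.to_dict())
    tables = CatalogTables(
        species=species_table,
        genomes=results["qc"],
        snvs=results["snv"],
        pangenomes=results["pangenome"],
    )
    return tables, manifest
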