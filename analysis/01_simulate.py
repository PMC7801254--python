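"""Generate the synthetic genome collection the downstream analyses use.

Writes genomes/, metadata.tsv, proteins.faa and truth.json under
results/collection. The collection has 5 species of 12 genomes each
(100 kb, inter-species divergence 10 %, intraspecies substitution rate
0.002/bp), with assembly incompleteness, occasional cross-species
contaminant contigs and isolate/MAG + continent metadata.
"""

from pathlib import Path

from gutcatalog.pipeline import PipelineConfig
from gutcatalog.pipeline import stage_simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "collection"

if __name__ == "__main__":
    cfg = PipelineConfig(seed=1)
    cfg.simulation.seed = 1
    records, truth, proteins = stage_simulate(cfg, OUT)
    n_species = len(set(truth.genome_species.values()))
    print(f"wrote {len(records)} genomes from {n_species} species to {OUT}")
    print(f"proteins: {len(proteins)}")
    planted = sum(len(v) for v in truth.snv_sites.values())
    print(f"planted segregating sites: {planted}")
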