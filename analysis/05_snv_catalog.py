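"""Construct the intraspecies SNV catalogs and score recovery.

Each species with >= 3 conspecific genomes contributes a catalog: members
are aligned to the species representative, substitutions are called
(indels never count), and a locus is kept when its alternate allele is
carried by >= 2 members. Entries are tagged continent- and genome-type-
specific, and per-continent contributions are normalized by genome counts.
"""

import json
from pathlib import Path

import pandas as pd

from gutcatalog.pipeline import PipelineConfig, stage_snv

OUT = Path(__file__).resolve().parent.parent / "results" / "collection"

if __name__ == "__main__":
    table = stage_snv(PipelineConfig(seed=1), OUT)
    print(f"catalog SNVs: {len(table)} across {table['species_id'].nunique()} species")
    n_cont = int(table["continent_specific"].sum())
    n_type = int(table["type_specific"].sum())
    print(f"continent-specific: {n_cont}; genome-type-specific: {n_type}")
    contrib = pd.read_csv(OUT / "snv_continent_contributions.tsv", sep="\t")
    per_cont = contrib.groupby("continent")["snvs_per_genome"].mean()
    print("mean continent-specific SNVs per genome:")
    print(per_cont.to_string())
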