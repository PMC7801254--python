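"""Quality-score every genome and apply the admission filter.

QS = completeness - 5 x contamination; a genome is admitted when
completeness > 50, contamination < 5 and QS > 50 (all strict). Also
reports the GSC quality tier (high requires >90 % completeness, <5 %
contamination, 5S+16S+23S rRNAs and >= 18 tRNAs).
"""

from pathlib import Path

from gutcatalog.pipeline import stage_qc

OUT = Path(__file__).resolve().parent.parent / "results" / "collection"

if __name__ == "__main__":
    report = stage_qc(OUT)
    n_pass = int(report["passes_filter"].sum())
    n_high = int((report["gsc_tier"] == "high").sum())
    print(f"{n_pass}/{len(report)} genomes pass the quality filter")
    print(f"{n_high} genomes reach the high (GSC) tier")
    print(f"report written to {OUT}/qc_report.tsv")
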