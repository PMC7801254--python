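# Methods

## Scope and model

`gutcatalog` reconstructs a species-level genome catalog from a collection
of assemblies with per-genome quality metadata. The operational species
definition is 95 % average nucleotide identity (ANI) over at least a 30 %
alignment fraction (AF); genomes inside a species are summarized by a
single representative, a nonredundant member count, a pan-genome and a
catalog of single-nucleotide variants (SNVs). Completeness and
contamination are treated as inputs (as estimated upstream by marker-gene
tools); the package never re-estimates them.

## Quality scoring and filtering

QS = completeness − 5 × contamination. The admission filter is strict on
all three axes: completeness > 50, contamination < 5, QS > 50, so boundary
values (exactly 50 % complete, exactly 5 % contaminated) fail. The
representative score adds 0.5 × log(N50). The log base is not fixed by the
formula's usual presentation; we use log₁₀ (configurable), which matches
the magnitude convention of standard dereplication scoring — at default
scale the term contributes 0–3.5 points, a tie-breaker against the
0–100-point quality term, which is the intended behaviour.

Strain heterogeneity is the percentage of qualifying pileup positions
(depth ≥ 10 after discarding alleles with mean base quality < 30) whose
minor-allele fraction is ≥ 0.2, with ≥ 100 qualifying positions required
for an estimate. This deliberately simplifies coding-region
nonsynonymous-substitution counting to an annotation-free polymorphic-site
fraction; the 0.2 minor-fraction default is a package choice, exposed as a
parameter.

## Sketching and ANI estimation

Sketches are bottom-s MinHash sets (s = 1,000) over canonical 21-mers
hashed with a seeded splitmix64 finalizer (hash seed fixed at 42 and
recorded; identical across a run so sketches are comparable). The Mash
distance −(1/k) ln(2j/(1+j)) uses the Jaccard index j estimated from the
merged bottom-s sketch; j = 0 maps to distance 1 by convention.

ANI between two genomes is estimated by cutting the query into
non-overlapping 1,000-bp fragments (trailing remainders merged so the
fragments tile each contig), anchoring each fragment on the target via
shared 15-mers with diagonal voting over both strands, and scoring the
anchored placement with a banded infix alignment (edlib). Fragments with
identity < 0.8 or fewer than 2 anchor votes are unmapped. ANI is the mean
identity of mapped fragments × 100; the directional coverages are the
mapped fraction of the query and the covered fraction of the target.
The reported AF follows a coverage mode: "larger" (maximum of the two,
the clustering default), "smaller", or "query". The 1-kb fragment length
suits the 50–500-kb genomes this package is exercised on and is
configurable; ties between candidate placements break toward the leftmost
target position for determinism.

Two AF conventions coexist deliberately: species clustering uses "larger",
while the cultured-status screen anchors AF on the representative's genome
length ("query" mode), matching the whole-genome-alignment convention of
reference screens. Both are parameters of `ani_af`.

## Species clustering

Stage one groups genomes by single-linkage on Mash distances at threshold
0.10 — a recall-oriented pre-filter whose only job is not to split true
species. Stage two, within each primary group, is greedy: genomes are
ranked by (isolate before MAG, representative score descending, genome id),
the best unassigned genome seeds a cluster and becomes its representative,
and every unassigned genome at ANI ≥ 95 and AF ≥ 0.30 to the seed joins.
This matches representative-selection semantics (the centroid is the best
genome, isolates always preferred) and is deterministic.

For collections above a chunk size, genomes are shuffled with the run
seed, chunks are clustered independently, the chunk representatives are
pooled and re-clustered, and members follow their chunk representative
into its final cluster. On collections whose species are separated well
beyond the 95 % threshold this reproduces the single-pass partition
exactly (asserted by test); score ties break lexicographically.

Conspecific dereplication follows the mechanism of a Mash-only
dereplication pass: greedy score-ordered collapse at Mash distance
≤ 0.001, the distance that corresponds to 99.9 % nucleotide identity. Per-
sample uniqueness (at most one genome per species per sample) applies to
frequency counting and rarefaction input, not to catalog membership.
Intraspecies dendrograms use complete linkage on Mash distances, cut at
0.03 (~97 % ANI) and 0.01 (~99 % ANI); singleton species report one
cluster by convention.

The adjusted Rand index is computed from the pair-counting contingency
table; scikit-learn's implementation serves only as an independent
cross-check in the tests.

## Pan-genomes and catalog merging

Protein clustering is greedy and incremental: sequences sorted by length
descending (ties by id), each joining the first centroid it matches at the
catalog identity over ≥ 80 % of the shorter sequence, else founding a
cluster. Identity is computed glocally — the shorter sequence aligned
into the longer — as matches / alignment columns. Catalog levels of
interest are 1.0 / 0.95 / 0.90 / 0.50. No paralog splitting: multiple
members from one genome count once in the presence matrix.

Per-species pan-genomes cluster conspecific proteins at 90 % identity; a
cluster present in ≥ 90 % of genomes is core, < 10 % rare, otherwise
intermediate. The "intraspecies" profile admits only genomes ≥ 90 %
complete and requires ≥ 10 of them. Normalized pan-genome size divides
the cluster count by the representative's gene count. Catalog merging
co-clusters the union of two centroid sets; the percent increase over the
baseline catalog is rounded to the nearest integer, matching the printed
precision of such summaries.

## SNV catalogs

Members are aligned to their species representative by exact 19-mer
anchors grouped into collinear diagonal runs per (contig, strand), each
run closed and extended with a banded infix alignment. Flank extension
beyond the outermost anchors follows the anchor diagonal and never crosses
the representative contig, so member sequence belonging elsewhere cannot
be forced into a window. Candidate blocks are reduced to a one-to-one
mapping on both axes: blocks are taken in score order, positions already
claimed are trimmed, and blocks more than half-claimed are dropped —
duplicate copies of a repeated segment therefore never contribute columns.

Pure edit distance cannot prefer two substitutions over an equal-cost
insertion + deletion pair, so nearby substitutions can surface as balanced
gaps. A smoothing pass re-pairs any gap that is rebalanced by the opposite
gap within 40 columns (both sides consume the same bases, so the pairing
is exact); unbalanced gaps — true indels of any length — are preserved and
never yield SNVs. Substitutions are aligned columns with both bases
present and differing, reported 1-based on the representative's forward
strand; for reverse-strand blocks the alternate allele is the complement
of the member base.

A species needs ≥ 3 conspecific genomes to build a catalog; a locus is
kept when one alternate allele is carried by ≥ 2 members. A member
carrying different alternates at one locus across its contigs (a
contamination artifact) tallies each allele independently. Specificity
flags mark loci whose carriers all share one continent or one genome type;
per-continent contributions divide continent-specific counts by the
continent's genome count. Pairwise densities (genomes ≥ 90 % complete,
≥ 10 per species, capped at the 1,000 best by representative score) use
the representative-axis aligned length as the denominator by default; the
published definition does not state its denominator, so a "genome"
(mean-length) mode is exposed as a switch.

## Diversity statistics

Geographic diversity is the Shannon index, natural log, over per-continent
proportions of samples containing the species; proportions are
renormalized over observed continents before the entropy (the raw mode is
available, since the original computation's normalization is unstated).
Rarefaction curves average cumulative distinct-species counts over seeded
random permutations (default 100 replicates; a hypergeometric closed form
backs the tests). Phylogenetic diversity sums branch lengths; PD_cultured
sums the edges of the subtree spanning the cultured leaves — an edge
counts when cultured leaves lie on both of its sides, so the root edge is
excluded unless it separates cultured leaves, which it cannot. Uncultured
monophyletic groups are the maximal internal nodes whose leaves are all
uncultured.

## Synthetic collections

The generator plants a root sequence, derives each species ancestor by
independent substitution at the inter-species divergence (default 0.10, so
ancestor pairs differ at ~2d(1−2d/3) ≈ 19 % of sites, far beyond the
species boundary; values ≤ 0.05 are rejected because they can leave pairs
above 95 % ANI). Conspecific genomes draw alternate alleles from a
species-level pool of segregating sites (per-genome carrier probability
0.3; pool size chosen so the expected per-genome substitution rate is the
configured 0.002/bp) — shared sites are what make ≥ 2-carrier SNV loci
common, mirroring real segregating variation. Incompleteness removes one
contiguous block whose edges become contig boundaries, so completeness
maps exactly to the retained fraction; contamination injects a foreign
contig from another species' ancestor; isolates receive complete rRNA/tRNA
complements while MAGs rarely do. Gene content is core families present
everywhere plus accessory families at 8 % presence, giving the bimodal
core/rare presence profile typical of prokaryotic pan-genomes; protein
families diverge 1.5 % per residue within and are unrelated between
(chance identity ≪ 50 %).

The truth object records species labels, every planted site with applied
and deletion-surviving carriers, per-genome contig layouts in ancestral
coordinates, gene presence, deleted and contaminant fractions. Identical
config and seed reproduce byte-identical outputs.

What the generator does not emulate — and what passing tests therefore do
not show about real data: read-level sequencing error, assembly-graph
artifacts, gene synteny and rearrangement, recombination and horizontal
transfer, chimeric binning beyond whole-contig contamination, and realistic
(megabase) genome sizes. Recovery being exact here demonstrates the
correctness of the rules and bookkeeping, not robustness to every
real-world failure mode.

## Problem sizes and determinism

The shipped analyses and acceptance checks run 5 species × 12 genomes of
100 kb for species recovery (with a chunked re-run at chunk size 20) and
3 species × 6 genomes of 50 kb, substitution-only, for SNV recovery —
sizes at which every pairwise quantity can be verified against planted
truth exactly. All randomness flows through explicit integer seeds
(numpy default_rng); pipeline stage outputs are pure functions of the
working directory plus seed, and the run manifest records SHA-256
checksums so identical re-runs can be verified byte for byte.

## Known limitations

- The fragment ANI estimator is not bit-compatible with the original
  fragment-mapping tools; it matches them in definition, not output.
- Greedy protein clustering approximates linear-time clustering engines;
  cluster counts can differ from either engine at the same identity.
- The balanced-gap smoothing in the aligner favours substitution
  interpretations within 40 columns; on genuinely indel-rich alignments
  this is a modelling choice, appropriate for the conspecific,
  substitution-dominated comparisons it serves.
- Strain heterogeneity ignores codon structure entirely.
- Taxonomy assignment, functional annotation, read classification and
  tree inference are out of scope; trees and quality estimates are inputs.
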