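"""Whole-genome alignment to the representative and SNV catalog rules."""

import numpy as np
import pytest

from gutcatalog.cluster import SpeciesCluster
from gutcatalog.io import GenomeRecord
from gutcatalog.sketch import reverse_complement
from gutcatalog.snv import (
    align_to_representative,
    build_species_snv_catalog,
    call_snvs,
    pairwise_snv_density,
    tag_specific_snvs,
)
from conftest import mutate_genome, random_genome


def _sub_keys(blocks):
    return {(s.rep_contig, s.position, s.ref, s.alt) for s in call_snvs(blocks)}


class TestAlignment:
    def test_identical_member_one_block_per_contig_all_match(self):
        rep = random_genome("rep", 30_000, seed=1, n_contigs=3)
        member = GenomeRecord("m", [(f"m_{c}", s) for c, s in rep.contigs])
        blocks = align_to_representative(member, rep)
        assert len(blocks) == 3
        for blk in blocks:
            assert blk.n_match == blk.n_aligned
        assert sum(b.n_aligned for b in blocks) == rep.length

    def test_planted_substitutions_are_exactly_the_mismatch_columns(self):
        rep = random_genome("rep", 20_000, seed=2)
        member, muts = mutate_genome(rep, 10 / 20_000, seed=3, genome_id="m")
        blocks = align_to_representative(member, rep)
        expected = {
            ("rep_c1", pos + 1, ref, alt) for _, pos, ref, alt in muts
        }
        assert _sub_keys(blocks) == expected

    def test_reverse_complement_member_gives_same_catalog(self):
        """Strand consistency: alt alleles are reported on the
        representative's forward strand."""
        rep = random_genome("rep", 20_000, seed=4)
        member, muts = mutate_genome(rep, 0.001, seed=5, genome_id="m")
        rc_member = GenomeRecord(
            "rc", [("rc_c1", reverse_complement(member.contigs[0][1]))]
        )
        fwd = _sub_keys(align_to_representative(member, rep))
        rc = _sub_keys(align_to_representative(rc_member, rep))
        assert fwd == rc and len(fwd) == len(muts)

    def test_duplicated_segment_covered_once(self):
        """One-to-one filtering removes the duplicate copy: each
        representative base is claimed by at most one block."""
        rep = random_genome("rep", 20_000, seed=6)
        seq = rep.contigs[0][1]
        dup_member = GenomeRecord("dup", [("dup_c1", seq + seq[5_000:8_000])])
        blocks = align_to_representative(dup_member, rep)
        claimed = np.zeros(rep.length, dtype=int)
        for blk in blocks:
            claimed[blk.rep_cols] += 1
        assert claimed.max() == 1
        assert _sub_keys(blocks) == set()

    def test_unrelated_member_yields_no_blocks(self):
        rep = random_genome("rep", 20_000, seed=7)
        other = random_genome("other", 20_000, seed=8)
        assert align_to_representative(other, rep) == []


class TestCallSnvs:
    def test_no_mismatches_empty_list(self):
        rep = random_genome("rep", 10_000, seed=9)
        member = GenomeRecord("m", [("m_c1", rep.contigs[0][1])])
        assert call_snvs(align_to_representative(member, rep)) == []

    def test_single_base_indel_is_not_an_snv(self):
        """A substitution plus a single-base insertion yields exactly one
        SNV; the indel column is skipped entirely."""
        rep = random_genome("rep", 10_000, seed=10)
        seq = list(rep.contigs[0][1])
        ref_base = seq[4_000]
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref_base]
        seq[4_000] = alt  # substitution
        seq.insert(7_000, "A")  # single-base insertion
        member = GenomeRecord("m", [("m_c1", "".join(seq))])
        subs = call_snvs(align_to_representative(member, rep))
        assert len(subs) == 1
        assert (subs[0].position, subs[0].ref, subs[0].alt) == (4_001, ref_base, alt)

    def test_single_base_deletion_is_not_an_snv(self):
        rep = random_genome("rep", 10_000, seed=11)
        seq = list(rep.contigs[0][1])
        del seq[5_000]
        member = GenomeRecord("m", [("m_c1", "".join(seq))])
        assert call_snvs(align_to_representative(member, rep)) == []

    def test_multi_base_indel_never_produces_snvs(self):
        rep = random_genome("rep", 10_000, seed=12)
        seq = list(rep.contigs[0][1])
        del seq[3_000:3_010]
        member = GenomeRecord("m", [("m_c1", "".join(seq))])
        assert call_snvs(align_to_representative(member, rep)) == []


def _planted_species(n_members=5, seed=20, length=20_000):
    """A species built by hand: shared sites with known carriers."""
    rng = np.random.default_rng(seed)
    rep = random_genome("rep", length, seed=seed)
    arr0 = np.array(list(rep.contigs[0][1]))
    sites = []
    for pos in rng.choice(length, size=30, replace=False):
        ref = arr0[pos]
        alt = [b for b in "ACGT" if b != ref][rng.integers(0, 3)]
        carriers = [f"m{i}" for i in range(n_members) if rng.random() < 0.4]
        sites.append((int(pos), str(ref), alt, carriers))
    members = []
    for i in range(n_members):
        arr = arr0.copy()
        for pos, ref, alt, carriers in sites:
            if f"m{i}" in carriers:
                arr[pos] = alt
        members.append(GenomeRecord(f"m{i}", [(f"m{i}_c1", "".join(arr))]))
    return rep, members, sites


class TestSpeciesCatalog:
    def test_species_with_two_genomes_is_skipped(self):
        rep = random_genome("rep", 10_000, seed=21)
        m = GenomeRecord("m", [("m_c1", rep.contigs[0][1])])
        cl = SpeciesCluster("s", "rep", ["rep", "m"])
        by_id = {"rep": rep, "m": m}
        assert build_species_snv_catalog(cl, by_id) is None

    def test_planted_recovery_and_carrier_rule(self):
        """Loci with >= 2 carriers are recovered exactly; single-carrier
        substitutions never enter the catalog."""
        rep, members, sites = _planted_species()
        by_id = {g.genome_id: g for g in [rep] + members}
        cl = SpeciesCluster("s", "rep", sorted(by_id))
        catalog = build_species_snv_catalog(cl, by_id)
        got = {(r.position, r.ref, r.alt) for r in catalog}
        expected = {
            (pos + 1, ref, alt)
            for pos, ref, alt, carriers in sites
            if len(carriers) >= 2
        }
        assert got == expected
        single = {
            (pos + 1, ref, alt)
            for pos, ref, alt, carriers in sites
            if len(carriers) == 1
        }
        assert got & single == set()

    def test_carriers_recorded_exactly(self):
        rep, members, sites = _planted_species(seed=22)
        by_id = {g.genome_id: g for g in [rep] + members}
        cl = SpeciesCluster("s", "rep", sorted(by_id))
        catalog = build_species_snv_catalog(cl, by_id)
        by_locus = {(r.position, r.alt): r.carriers for r in catalog}
        for pos, ref, alt, carriers in sites:
            if len(carriers) >= 2:
                assert by_locus[(pos + 1, alt)] == sorted(carriers)


class TestSpecificity:
    def _catalog(self):
        rep, members, sites = _planted_species(seed=23)
        by_id = {g.genome_id: g for g in [rep] + members}
        cl = SpeciesCluster("s", "rep", sorted(by_id))
        return build_species_snv_catalog(cl, by_id)

    def test_mixed_continents_not_specific(self):
        catalog = self._catalog()
        meta = {f"m{i}": ("Europe" if i % 2 else "Asia", "MAG") for i in range(5)}
        tagged, _ = tag_specific_snvs(catalog, meta)
        mixed = [r for r in tagged if len(r.continents) > 1]
        assert mixed and all(not r.continent_specific for r in mixed)

    def test_all_mag_carriers_are_type_specific(self):
        catalog = self._catalog()
        meta = {f"m{i}": ("Europe", "MAG") for i in range(5)}
        tagged, _ = tag_specific_snvs(catalog, meta)
        assert all(r.type_specific and r.genome_types == {"MAG"} for r in tagged)

    def test_sum_rule(self):
        catalog = self._catalog()
        meta = {f"m{i}": ("Europe" if i % 2 else "Asia", "MAG") for i in range(5)}
        tagged, _ = tag_specific_snvs(catalog, meta)
        n_spec = sum(r.continent_specific for r in tagged)
        n_shared = sum(not r.continent_specific for r in tagged)
        assert n_spec + n_shared == len(tagged)

    def test_per_continent_contribution_normalization(self):
        """10 Africa-specific SNVs over 2 genomes beat 30 Europe-specific
        SNVs over 20 genomes (5.0 vs 1.5 per genome)."""
        from gutcatalog.snv import SNVRecord

        catalog = [
            SNVRecord("s", "c", i + 1, "A", "C", ["gA1", "gA2"])
            for i in range(10)
        ] + [
            SNVRecord("s", "c", 100 + i, "A", "G", ["gE1", "gE2"])
            for i in range(30)
        ]
        meta = {"gA1": ("Africa", "MAG"), "gA2": ("Africa", "MAG"),
                "gE1": ("Europe", "MAG"), "gE2": ("Europe", "MAG")}
        counts = {"Africa": 2, "Europe": 20}
        _, contrib = tag_specific_snvs(catalog, meta, genomes_per_continent=counts)
        assert contrib["Africa"] == pytest.approx(5.0)
        assert contrib["Europe"] == pytest.approx(1.5)
        assert contrib["Africa"] > contrib["Europe"]


class TestPairwiseDensity:
    def _species(self, n=10, length=20_000, seed=30, rate=0.001):
        rep = random_genome("m0", length, seed=seed, completeness=95.0)
        members = [rep]
        for i in range(1, n):
            m, _ = mutate_genome(rep, rate, seed=seed + i, genome_id=f"m{i}")
            m.completeness = 95.0
            members.append(m)
        by_id = {g.genome_id: g for g in members}
        cl = SpeciesCluster("s", "m0", sorted(by_id))
        return cl, by_id

    def test_small_species_gated_out(self):
        cl, by_id = self._species(n=5)
        assert pairwise_snv_density(cl, by_id, min_genomes=10) is None

    def test_identical_pair_density_zero(self):
        rep = random_genome("m0", 10_000, seed=31, completeness=95.0)
        twin = GenomeRecord("m1", [("m1_c1", rep.contigs[0][1])], completeness=95.0)
        more = [rep, twin]
        by_id = {g.genome_id: g for g in more}
        cl = SpeciesCluster("s", "m0", sorted(by_id))
        df = pairwise_snv_density(cl, by_id, min_genomes=2)
        assert df["density_per_kb"].iloc[0] == 0.0

    def test_forced_arithmetic_two_snvs_per_two_kb(self):
        rep = random_genome("m0", 2_000, seed=32, completeness=95.0)
        seq = list(rep.contigs[0][1])
        for pos in (500, 1_500):
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        m1 = GenomeRecord("m1", [("m1_c1", "".join(seq))], completeness=95.0)
        by_id = {"m0": rep, "m1": m1}
        cl = SpeciesCluster("s", "m0", ["m0", "m1"])
        df = pairwise_snv_density(cl, by_id, min_genomes=2)
        assert df["aligned_bp"].iloc[0] == 2_000
        assert df["density_per_kb"].iloc[0] == pytest.approx(1.0)

    def test_density_symmetry_on_mutation_only_pairs(self):
        rep = random_genome("a", 20_000, seed=33)
        m, _ = mutate_genome(rep, 0.002, seed=34, genome_id="b")
        from gutcatalog.snv import align_to_representative, call_snvs

        d_ab = len(call_snvs(align_to_representative(rep, m)))
        d_ba = len(call_snvs(align_to_representative(m, rep)))
        assert d_ab == d_ba

    def test_two_populations_ordering(self):
        """Within-population SNV density is below cross-population density
        when two subpopulations diverge at different rates."""
        base = random_genome("m0", 20_000, seed=35, completeness=95.0)
        pop_a = [base] + [
            mutate_genome(base, 0.0005, seed=36 + i, genome_id=f"a{i}")[0]
            for i in range(2)
        ]
        far, _ = mutate_genome(base, 0.01, seed=40, genome_id="far")
        pop_b = [far] + [
            mutate_genome(far, 0.0005, seed=41 + i, genome_id=f"b{i}")[0]
            for i in range(2)
        ]
        for g in pop_a + pop_b:
            g.completeness = 95.0
        by_id = {g.genome_id: g for g in pop_a + pop_b}
        cl = SpeciesCluster("s", "m0", sorted(by_id))
        df = pairwise_snv_density(cl, by_id, min_genomes=2)
        pop_of = {g.genome_id: ("A" if g in pop_a else "B") for g in pop_a + pop_b}
        within = df[[pop_of[a] == pop_of[b] for a, b in zip(df.genome_a, df.genome_b)]]
        across = df[[pop_of[a] != pop_of[b] for a, b in zip(df.genome_a, df.genome_b)]]
        assert within["density_per_kb"].median() < across["density_per_kb"].median()
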