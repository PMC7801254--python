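"""Protein clustering, pan-genome classes, HQ subsets and catalog merging."""

import numpy as np
import pytest
from Bio import Align

from gutcatalog.pangenome import (
    ProteinSeq,
    build_pangenome,
    classify_frequency,
    cluster_proteins,
    hq_subset,
    merge_catalogs,
    merge_percent_increase,
    normalized_pangenome_size,
    pair_identity_coverage,
)
from gutcatalog.synthetic import SimulationConfig, generate_collection, generate_protein_set

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _random_protein(rng, length=120):
    return "".join(rng.choice(AA, size=length))


def _mutate_protein(rng, seq, n_mut):
    arr = list(seq)
    for p in rng.choice(len(arr), size=n_mut, replace=False):
        arr[p] = rng.choice([a for a in AA if a != arr[p]])
    return "".join(arr)


def _ps(seq_id, seq, genome="g1", species="s1"):
    return ProteinSeq(seq_id, genome, species, seq)


class TestPairIdentity:
    def test_agrees_with_biopython_global_alignment(self):
        """Identity of a constructed pair matches an independent aligner."""
        rng = np.random.default_rng(0)
        a = _random_protein(rng, 100)
        b = _mutate_protein(rng, a, 15)
        ident, cov = pair_identity_coverage(a, b)
        aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                        mismatch_score=0, gap_score=-1)
        aln = aligner.align(a, b)[0]
        oracle_ident = aln.counts().identities / len(a)
        assert ident == pytest.approx(oracle_ident, abs=0.01)
        assert cov == pytest.approx(1.0)


class TestClusterProteins:
    def test_identical_sequences_form_one_cluster(self):
        rng = np.random.default_rng(1)
        seq = _random_protein(rng)
        seqs = [_ps(f"p{i}", seq) for i in range(5)]
        clusters = cluster_proteins(seqs, identity=1.0)
        assert len(clusters) == 1 and clusters[0].size == 5

    def test_85_percent_pair_splits_at_90_joins_at_50(self):
        rng = np.random.default_rng(2)
        a = _random_protein(rng, 100)
        b = _mutate_protein(rng, a, 15)  # 85 % identity
        seqs = [_ps("a", a), _ps("b", b)]
        assert len(cluster_proteins(seqs, identity=0.90)) == 2
        assert len(cluster_proteins(seqs, identity=0.50)) == 1

    @pytest.mark.parametrize("identity", [1.0, 0.9, 0.5])
    def test_member_count_conserved(self, identity):
        rng = np.random.default_rng(3)
        fams = [_random_protein(rng, rng.integers(60, 150)) for _ in range(6)]
        seqs = [
            _ps(f"f{i}m{j}", _mutate_protein(rng, fam, 2))
            for i, fam in enumerate(fams)
            for j in range(4)
        ]
        clusters = cluster_proteins(seqs, identity=identity)
        assert sum(c.size for c in clusters) == len(seqs)

    def test_input_order_irrelevant(self):
        rng = np.random.default_rng(4)
        fam = _random_protein(rng, 90)
        seqs = [_ps(f"p{i}", _mutate_protein(rng, fam, i)) for i in range(6)]
        a = cluster_proteins(seqs, identity=0.9)
        b = cluster_proteins(list(reversed(seqs)), identity=0.9)
        sig = lambda cls: sorted(tuple(sorted(m.seq_id for m in c.members)) for c in cls)
        assert sig(a) == sig(b)

    def test_non_amino_acid_characters_rejected(self):
        with pytest.raises(ValueError, match="bad_seq"):
            cluster_proteins([_ps("bad_seq", "MKV123LLAA")], identity=0.9)


class TestPanGenome:
    def _proteins(self, presence):
        """presence: dict family -> list of genomes carrying it."""
        rng = np.random.default_rng(5)
        fams = {f: _random_protein(rng, 100) for f in presence}
        return {
            g: [
                _ps(f"{g}|{f}", fams[f], genome=g)
                for f, gs in presence.items()
                if g in gs
            ]
            for g in {g for gs in presence.values() for g in gs}
        }

    def test_clonal_genomes_all_core_normalized_one(self):
        genomes = [f"g{i}" for i in range(10)]
        presence = {f"fam{j}": genomes for j in range(8)}
        pg = build_pangenome("s1", self._proteins(presence))
        assert (pg.frequency_class == "core").all()
        assert normalized_pangenome_size(pg, 8) == pytest.approx(1.0)

    def test_nine_of_ten_is_core(self):
        genomes = [f"g{i}" for i in range(10)]
        presence = {"full": genomes, "nine": genomes[:9]}
        pg = build_pangenome("s1", self._proteins(presence))
        assert pg.frequency_class["cluster_000001"] == "core"
        assert (pg.frequency_class == "core").all()

    def test_one_of_eleven_is_rare(self):
        genomes = [f"g{i}" for i in range(11)]
        presence = {"full": genomes, "single": genomes[:1]}
        pg = build_pangenome("s1", self._proteins(presence))
        counts = pg.class_counts()
        assert counts.get("rare", 0) == 1

    @pytest.mark.parametrize(
        "fraction,expected",
        [(0.90, "core"), (0.899, "intermediate"), (0.10, "intermediate"),
         (0.099, "rare"), (1.0, "core"), (0.0, "rare")],
    )
    def test_frequency_boundaries(self, fraction, expected):
        assert classify_frequency(fraction) == expected

    def test_intraspecies_profile_gates_small_species(self):
        genomes = [f"g{i}" for i in range(5)]
        presence = {"fam": genomes}
        pg = build_pangenome(
            "s1", self._proteins(presence), profile="intraspecies",
            completeness={g: 99.0 for g in genomes},
        )
        assert pg is None

    def test_intraspecies_profile_drops_incomplete_genomes(self):
        genomes = [f"g{i}" for i in range(12)]
        presence = {"fam": genomes}
        completeness = {g: (85.0 if g in ("g0", "g1") else 95.0) for g in genomes}
        pg = build_pangenome(
            "s1", self._proteins(presence), profile="intraspecies",
            completeness=completeness,
        )
        assert pg is not None
        assert set(pg.presence.columns) == set(genomes) - {"g0", "g1"}

    def test_normalized_size_with_accessory_inflation(self):
        pg_genomes = [f"g{i}" for i in range(10)]
        presence = {f"core{j}": pg_genomes for j in range(10)}
        presence.update({f"acc{j}": pg_genomes[j : j + 1] for j in range(2)})
        pg = build_pangenome("s1", self._proteins(presence))
        # 12 clusters over a 10-gene representative = 1.2
        assert normalized_pangenome_size(pg, 10) == pytest.approx(1.2)

    def test_zero_representative_genes_rejected(self):
        presence = {"fam": ["g0"]}
        pg = build_pangenome("s1", self._proteins(presence))
        with pytest.raises(ValueError):
            normalized_pangenome_size(pg, 0)

    def test_default_synthetic_species_presence_is_bimodal(self):
        """Core and low-frequency accessory genes dominate the presence
        histogram, with few intermediate-frequency clusters."""
        cfg = SimulationConfig(n_species=1, genomes_per_species=(12, 12),
                               genome_length=20_000, seed=31,
                               incompleteness_range=(0.0, 0.0),
                               contamination_prob=0.0)
        records, truth = generate_collection(cfg)
        proteins = generate_protein_set(cfg, truth)
        member = {r.genome_id: [] for r in records}
        for p in proteins:
            member[p.genome_id].append(p)
        pg = build_pangenome("sp01", member)
        frac = pg.presence.mean(axis=1)
        n_high = int(((frac >= 0.9)).sum())
        n_low = int((frac < 0.1).sum())
        n_mid = len(frac) - n_high - n_low
        assert n_high >= 0.9 * cfg.n_core_genes  # core families land high
        assert n_low > 0
        assert n_high + n_low > 2 * n_mid


class TestHqSubset:
    def _cluster(self, members):
        from gutcatalog.pangenome import ProteinCluster

        return ProteinCluster("c1", members[0].seq_id, members, 0.9)

    def test_singleton_excluded(self):
        cl = self._cluster([_ps("p1", "MKVLA" * 10)])
        assert hq_subset([cl]) == []

    def test_two_members_same_genome_excluded(self):
        cl = self._cluster([
            _ps("p1", "MKVLA" * 10, genome="g1"),
            _ps("p2", "MKVLA" * 10, genome="g1"),
        ])
        assert hq_subset([cl]) == []

    def test_two_genomes_same_species_included(self):
        cl = self._cluster([
            _ps("p1", "MKVLA" * 10, genome="g1", species="s1"),
            _ps("p2", "MKVLA" * 10, genome="g2", species="s1"),
        ])
        assert hq_subset([cl]) == [cl]

    def test_two_genomes_different_species_excluded(self):
        cl = self._cluster([
            _ps("p1", "MKVLA" * 10, genome="g1", species="s1"),
            _ps("p2", "MKVLA" * 10, genome="g2", species="s2"),
        ])
        assert hq_subset([cl]) == []


class TestMerge:
    def test_catalog_merged_with_itself(self):
        rng = np.random.default_rng(6)
        cat = [_ps(f"p{i}", _random_protein(rng, 100)) for i in range(8)]
        stats = merge_catalogs(cat, cat)
        assert stats.total == len(cat)
        assert stats.overlap == len(cat)
        assert stats.pct_increase == 0
        assert stats.pct_b_covered == pytest.approx(100.0)

    def test_disjoint_catalogs_add_up(self):
        rng = np.random.default_rng(7)
        a = [_ps(f"a{i}", _random_protein(rng, 100)) for i in range(5)]
        b = [_ps(f"b{i}", _random_protein(rng, 100)) for i in range(7)]
        stats = merge_catalogs(a, b)
        assert stats.total == 12
        assert stats.overlap == 0

    def test_counts_only_percent_increase(self):
        assert merge_percent_increase(7_063_981, 15_217_595) == 115

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            merge_catalogs([], [_ps("p", "MKVLA" * 10)])
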