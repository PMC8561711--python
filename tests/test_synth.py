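import numpy as np
import pytest

from ppfm.io import SequenceRecord
from ppfm.synth import (
    DivergenceSpec,
    GenomeSpec,
    PlantSpec,
    diverge_genome,
    forge_adh_family,
    forge_genome,
    implant_cluster,
)
from tests.conftest import make_genome


def _gc(seq: str) -> float:
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def _mismatch_fraction(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b)) / len(a)


class TestForgeGenome:
    def test_gene_and_protein_counts(self):
        spec = GenomeSpec(1, (100_000,), 80, gc_target=66.0, seed=7)
        g = forge_genome(spec, "g")
        assert len(g.genes) == 80
        assert len(g.proteins) == 80
        assert g.size_bp == 100_000

    def test_deterministic_for_fixed_seed(self):
        spec = GenomeSpec(2, (40_000, 20_000), 40, gc_target=68.0, seed=3)
        a, b = forge_genome(spec, "g"), forge_genome(spec, "g")
        assert all(
            a.replicons[r].seq == b.replicons[r].seq for r in a.replicons
        )
        assert a.genes == b.genes

    def test_distinct_seeds_differ(self):
        s1 = GenomeSpec(1, (30_000,), 20, seed=1)
        s2 = GenomeSpec(1, (30_000,), 20, seed=2)
        a, b = forge_genome(s1), forge_genome(s2)
        assert a.replicons[next(iter(a.replicons))].seq != b.replicons[
            next(iter(b.replicons))
        ].seq

    def test_gc_tracks_target(self):
        # direct base-count oracle on the forged output
        g = forge_genome(GenomeSpec(1, (100_000,), 80, gc_target=66.0, seed=7))
        gc = _gc(g.replicons[next(iter(g.replicons))].seq)
        assert 65.0 <= gc <= 67.0

    def test_proteins_have_no_internal_stops(self, small_genome):
        assert all("*" not in p.seq for p in small_genome.proteins.values())

    def test_overcrowded_replicon_errors(self):
        spec = GenomeSpec(1, (5_000,), 50, gene_length_range=(300, 600), seed=0)
        with pytest.raises(ValueError, match="cannot be placed"):
            forge_genome(spec)


class TestDiverge:
    def test_p_zero_is_identity(self, small_genome):
        res = diverge_genome(small_genome, DivergenceSpec(0.0, seed=5))
        for rid, rep in small_genome.replicons.items():
            assert res.genome.replicons[rid].seq == rep.seq
        assert res.realized_p == 0.0

    def test_realized_mismatch_matches_p(self):
        g = make_genome(length=100_000, n_genes=80, seed=7, genome_id="a")
        res = diverge_genome(g, DivergenceSpec(0.05, seed=11), "b")
        rid = next(iter(g.replicons))
        mm = _mismatch_fraction(g.replicons[rid].seq, res.genome.replicons[rid].seq)
        assert abs(mm - 0.05) <= 0.005
        assert abs(res.realized_p - 0.05) <= 0.005

    def test_two_independent_divergences_compose(self):
        # two independent 5% substitution processes leave ~1-0.95^2 (plus
        # back-mutation coincidences) mutual divergence ~ 0.0975
        g = make_genome(length=100_000, n_genes=80, seed=7)
        d1 = diverge_genome(g, DivergenceSpec(0.05, seed=21), "x")
        d2 = diverge_genome(g, DivergenceSpec(0.05, seed=22), "y")
        rid = next(iter(g.replicons))
        mm = _mismatch_fraction(
            d1.genome.replicons[rid].seq, d2.genome.replicons[rid].seq
        )
        assert abs(mm - 0.0975) <= 0.01

    def test_no_internal_stops_after_divergence(self, small_genome):
        res = diverge_genome(small_genome, DivergenceSpec(0.10, seed=13))
        assert all("*" not in p.seq for p in res.genome.proteins.values())

    def test_indels_remap_coordinates(self, small_genome):
        res = diverge_genome(
            small_genome, DivergenceSpec(0.02, indel_rate=0.5, seed=17)
        )
        assert res.n_indels > 0
        # every remapped gene still translates cleanly (frames preserved)
        assert all("*" not in p.seq for p in res.genome.proteins.values())
        for gene in res.genome.genes:
            rep = res.genome.replicons[gene.replicon_id]
            assert 1 <= gene.start <= gene.end <= len(rep.seq)


class TestImplant:
    def test_full_cluster_implanted(self, small_genome, mxa_cluster):
        res = implant_cluster(small_genome, PlantSpec(mxa_cluster, 1.0), seed=2)
        assert len(res.implanted) == 14

    def test_partial_implant_count(self, small_genome, mxa_cluster):
        res = implant_cluster(
            small_genome, PlantSpec(mxa_cluster, 11 / 14), seed=2
        )
        assert len(res.implanted) == 11

    def test_contiguous_implants_consecutive_ranks(self, small_genome, mxa_cluster):
        res = implant_cluster(
            small_genome, PlantSpec(mxa_cluster, 1.0, contiguous=True), seed=2
        )
        ranks = sorted(
            res.genome.gene(i.gene_id).rank for i in res.implanted
        )
        assert ranks == list(range(ranks[0], ranks[0] + 14))

    def test_intervening_spacers(self, small_genome, mxa_cluster):
        res = implant_cluster(
            small_genome,
            PlantSpec(mxa_cluster, 2 / 14, contiguous=True, intervening_genes=10),
            seed=2,
        )
        r1, r2 = sorted(res.genome.gene(i.gene_id).rank for i in res.implanted)
        assert r2 - r1 - 1 == 10

    def test_zero_fraction_warns_and_leaves_unchanged(self, small_genome, mxa_cluster):
        with pytest.warns(UserWarning, match="0 genes"):
            res = implant_cluster(small_genome, PlantSpec(mxa_cluster, 0.0))
        assert res.genome is small_genome
        assert res.implanted == ()

    def test_implanted_proteins_in_proteome(self, small_genome, mxa_cluster):
        res = implant_cluster(small_genome, PlantSpec(mxa_cluster, 1.0), seed=2)
        by_name = {g.name: g.protein.seq for g in mxa_cluster.genes}
        for imp in res.implanted:
            assert res.genome.proteins[imp.gene_id].seq == by_name[imp.gene_name]


class TestAdhFamily:
    def test_zero_divergence_copies(self, anchors):
        fam = forge_adh_family(anchors[0], n=5, divergence=0.0, seed=1)
        assert len(fam.records) == 5
        assert all(r.seq == anchors[0].seq for r in fam.records)

    def test_overrides_planted_exactly(self, anchors):
        fam = forge_adh_family(
            anchors[0], n=50, divergence=0.1, residue_overrides={301: "D"}, seed=3
        )
        assert all(r.seq[300] == "D" for r in fam.records)
        assert all(v == {301: "D"} for v in fam.planted_residues.values())

    def test_override_beyond_length_errors(self):
        anchor = SequenceRecord(id="a", seq="MKV" * 10, alphabet="aa")
        with pytest.raises(ValueError, match="beyond"):
            forge_adh_family(anchor, 1, 0.0, residue_overrides={100: "D"})

    def test_realized_divergence_near_requested(self, anchors):
        fam = forge_adh_family(anchors[0], n=20, divergence=0.1, seed=5)
        mean_div = np.mean(list(fam.realized_divergence.values()))
        assert abs(mean_div - 0.1) < 0.01
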