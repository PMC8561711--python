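import numpy as np
import pytest

from ppfm.io import Genome, SequenceRecord
from ppfm.screen import (
    HitRecord,
    cluster_completeness,
    context_check,
    load_clusters,
    presence_absence,
    protein_identity_search,
)
from ppfm.synth import (
    PlantSpec,
    implant_cluster,
    mutate_protein,
    random_protein,
)
from tests.conftest import make_genome


def _proteome_genome(genome_id, proteins):
    return Genome(
        genome_id=genome_id,
        replicons={},
        proteins={p.id: p for p in proteins},
    )


class TestIdentitySearch:
    def test_exact_copy_hits_at_100(self):
        rng = np.random.default_rng(0)
        query = SequenceRecord(id="q", seq=random_protein(rng, 250), alphabet="aa")
        target = SequenceRecord(id="t", seq=query.seq, alphabet="aa")
        decoy = SequenceRecord(id="d", seq=random_protein(rng, 250), alphabet="aa")
        hits = protein_identity_search([query], [target, decoy])
        assert len(hits) == 1
        assert hits[0].target_gene_id == "t"
        assert hits[0].identity == pytest.approx(100.0)

    def test_distant_homolog_not_retained(self):
        # best target at ~40% identity: below the 50% cut
        rng = np.random.default_rng(1)
        base = random_protein(rng, 300)
        query = SequenceRecord(id="q", seq=base, alphabet="aa")
        far = SequenceRecord(
            id="far", seq=mutate_protein(base, 0.60, rng), alphabet="aa"
        )
        hits = protein_identity_search([query], [far])
        assert hits == []

    def test_dedup_keeps_highest_identity(self):
        rng = np.random.default_rng(2)
        base = random_protein(rng, 300)
        query = SequenceRecord(id="q", seq=base, alphabet="aa")
        close = SequenceRecord(
            id="close", seq=mutate_protein(base, 0.05, rng), alphabet="aa"
        )
        farther = SequenceRecord(
            id="farther", seq=mutate_protein(base, 0.20, rng), alphabet="aa"
        )
        hits = protein_identity_search([query], [farther, close])
        assert len(hits) == 1
        assert hits[0].target_gene_id == "close"

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        base = random_protein(rng, 250)
        query = SequenceRecord(id="q", seq=base, alphabet="aa")
        targets = [
            SequenceRecord(id=f"t{i}", seq=mutate_protein(base, 0.1, rng), alphabet="aa")
            for i in range(4)
        ]
        a = protein_identity_search([query], targets)
        b = protein_identity_search([query], targets[::-1])
        assert a == b


class TestPresenceAbsence:
    def test_full_and_partial_implants(self, small_genome, mxa_cluster):
        full = implant_cluster(small_genome, PlantSpec(mxa_cluster, 1.0), seed=2)
        part = implant_cluster(
            small_genome, PlantSpec(mxa_cluster, 11 / 14), seed=3,
            genome_id="partial",
        )
        empty = make_genome(seed=77, genome_id="empty")
        matrix = presence_absence(
            [mxa_cluster], [full.genome, part.genome, empty]
        )
        assert matrix.df["small"].sum() == 14
        assert matrix.df["partial"].sum() == 11
        assert matrix.df["empty"].sum() == 0

    def test_provenance_for_every_hit(self, small_genome, mxa_cluster):
        res = implant_cluster(small_genome, PlantSpec(mxa_cluster, 0.5), seed=4)
        matrix = presence_absence([mxa_cluster], [res.genome])
        ones = [
            (r, c)
            for r in matrix.df.index
            for c in matrix.df.columns
            if matrix.df.loc[r, c] == 1
        ]
        assert set(ones) == set(matrix.provenance)


class TestClusterCompleteness:
    @pytest.mark.parametrize(
        "present,total,pct,conserved",
        [
            (11, 14, 78.6, True),
            (10, 14, 71.4, False),
            (3, 4, 75.0, False),  # strict > 75
            (14, 14, 100.0, True),
        ],
    )
    def test_boundaries(self, mxa_cluster, present, total, pct, conserved):
        cluster = (
            mxa_cluster
            if total == 14
            else type(mxa_cluster)(name="sub", genes=mxa_cluster.genes[:total])
        )
        cells = [1] * present + [0] * (total - present)
        got_pct, got_flag = cluster_completeness(cluster, cells)
        assert got_pct == pytest.approx(pct, abs=0.05)
        assert got_flag is conserved

    def test_monotone_in_presence(self, mxa_cluster):
        flags = [
            cluster_completeness(mxa_cluster, [1] * k + [0] * (14 - k))[1]
            for k in range(15)
        ]
        assert flags == sorted(flags)

    def test_essential_mode(self, mxa_cluster):
        # 12/14 present but an essential gene missing
        cells = {g.name: 1 for g in mxa_cluster.genes}
        cells[mxa_cluster.genes[0].name] = 0
        cells[mxa_cluster.genes[5].name] = 0
        pct, conserved = cluster_completeness(
            mxa_cluster, cells, require_essential=True
        )
        assert pct > 75 and not conserved


class TestContextCheck:
    def _genome_with_implants(self, small_genome, mxa_cluster, intervening):
        trio = type(mxa_cluster)(name="xox", genes=mxa_cluster.genes[:3])
        return implant_cluster(
            small_genome,
            PlantSpec(trio, 1.0, contiguous=True, intervening_genes=intervening),
            seed=6,
        )

    def _hits(self, implant_result):
        return {
            i.gene_name: HitRecord(
                query_gene=i.gene_name,
                target_gene_id=i.gene_id,
                identity=100.0,
                evalue=0.0,
                bitscore=500.0,
            )
            for i in implant_result.implanted
        }

    def test_consecutive_cluster_passes(self, small_genome, mxa_cluster):
        res = self._genome_with_implants(small_genome, mxa_cluster, 0)
        hits = self._hits(res)
        anchor, *partners = hits.values()
        assert context_check(anchor, partners, res.genome, max_intervening=5)

    def test_distant_partner_fails(self, small_genome, mxa_cluster):
        res = self._genome_with_implants(small_genome, mxa_cluster, 10)
        hits = self._hits(res)
        anchor, *partners = hits.values()
        assert not context_check(anchor, partners, res.genome, max_intervening=5)

    def test_partner_on_other_replicon_fails(self):
        from ppfm.io import GeneRecord, assign_ranks

        genes = assign_ranks(
            [
                GeneRecord("anchor", "r1", 100, 400, "+"),
                GeneRecord("partner", "r2", 100, 400, "+"),
            ]
        )
        genome = Genome(genome_id="g", replicons={}, genes=genes)
        anchor = HitRecord("xoxF", "anchor", 100.0, 0.0, 500.0)
        partner = HitRecord("xoxG", "partner", 100.0, 0.0, 500.0)
        assert not context_check(anchor, [partner], genome)


class TestRecallSpecificity:
    def test_implants_recovered_decoys_clean(self, mxa_cluster):
        queries = [
            SequenceRecord(id=g.name, seq=g.protein.seq, alphabet="aa")
            for g in mxa_cluster.genes[:5]
        ]
        rng = np.random.default_rng(50)
        for seed in range(5):
            # homologs at 25% divergence + decoys
            proteome = [
                SequenceRecord(
                    id=f"hom{i}",
                    seq=mutate_protein(q.seq, 0.25, np.random.default_rng(seed * 10 + i)),
                    alphabet="aa",
                )
                for i, q in enumerate(queries)
            ] + [
                SequenceRecord(id=f"d{i}", seq=random_protein(rng, 260), alphabet="aa")
                for i in range(10)
            ]
            hits = protein_identity_search(queries, proteome)
            assert len(hits) == len(queries)
            assert all(h.target_gene_id.startswith("hom") for h in hits)


def test_load_clusters_yaml(tmp_path, mxa_cluster):
    from ppfm.io import write_fasta

    write_fasta([g.protein for g in mxa_cluster.genes], tmp_path / "mxa.faa")
    (tmp_path / "clusters.yaml").write_text(
        "clusters:\n"
        "  - name: mxa\n"
        "    fasta: mxa.faa\n"
        "    genes:\n"
        + "".join(
            f"      - {{name: {g.name}, essential: {str(g.essential).lower()}}}\n"
            for g in mxa_cluster.genes
        )
    )
    clusters = load_clusters(tmp_path / "clusters.yaml")
    assert len(clusters) == 1
    assert clusters[0].gene_names() == [g.name for g in mxa_cluster.genes]
    assert clusters[0].genes[0].essential
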