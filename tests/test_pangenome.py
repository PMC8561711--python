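from io import StringIO

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import TreeNode

from ppfm.io import SequenceRecord
from ppfm.pangenome import (
    binary_distance_tree,
    cluster_proteomes,
    clustering_identity,
    core_concat_tree,
    nj_tree,
    pan_matrix,
    partition_families,
    robinson_foulds,
)
from ppfm.synth import forge_clade_scenario, forge_proteome_set, random_protein


def brute_force_partition(proteomes, min_identity=50.0):
    """Independent oracle: all-vs-all graph, single-linkage components."""
    import networkx as nx

    entries = [
        (g, p) for g, prots in proteomes.items() for p in prots
    ]
    graph = nx.Graph()
    for _, p in entries:
        graph.add_node(p.id)
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            a, b = entries[i][1], entries[j][1]
            if clustering_identity(a.seq, b.seq) >= min_identity:
                graph.add_edge(a.id, b.id)
    return {frozenset(c) for c in nx.connected_components(graph)}


class TestClustering:
    def test_identical_proteomes_one_family_per_protein(self):
        rng = np.random.default_rng(0)
        prots = [
            SequenceRecord(id=f"p{i}", seq=random_protein(rng, 200), alphabet="aa")
            for i in range(10)
        ]
        proteomes = {
            g: [SequenceRecord(id=f"{g}_{p.id}", seq=p.seq, alphabet="aa") for p in prots]
            for g in ("G1", "G2", "G3")
        }
        families = cluster_proteomes(proteomes)
        assert len(families) == 10
        assert all(len(f) == 3 for f in families)

    def test_disjoint_proteomes_all_singletons(self):
        rng = np.random.default_rng(1)
        proteomes = {
            g: [
                SequenceRecord(
                    id=f"{g}_p{i}", seq=random_protein(rng, 200), alphabet="aa"
                )
                for i in range(5)
            ]
            for g in ("G1", "G2")
        }
        families = cluster_proteomes(proteomes)
        assert len(families) == 10
        assert all(len(f) == 1 for f in families)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        sc = forge_proteome_set(
            n_genomes=3, n_core=10, n_unique=5, divergence=0.05, seed=seed
        )
        greedy = {
            frozenset(pid for _, pid in f.members)
            for f in cluster_proteomes(sc.proteomes)
        }
        assert greedy == brute_force_partition(sc.proteomes)

    def test_every_protein_in_exactly_one_family(self):
        sc = forge_proteome_set(seed=3)
        families = cluster_proteomes(sc.proteomes)
        all_members = [pid for f in families for _, pid in f.members]
        n_proteins = sum(len(v) for v in sc.proteomes.values())
        assert len(all_members) == n_proteins
        assert len(set(all_members)) == n_proteins

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            cluster_proteomes({})


class TestPartition:
    def test_planted_counts_recovered(self):
        sc = forge_proteome_set(n_genomes=4, n_core=20, n_unique=5, seed=7)
        families = cluster_proteomes(sc.proteomes)
        profile = partition_families(families, list(sc.proteomes))
        assert profile.n_core == 20
        assert profile.n_accessory == 0
        assert all(v == 5 for v in profile.n_unique_per_genome.values())
        assert profile.pan_total == 20 + 4 * 5

    def test_identical_proteomes_all_core(self):
        rng = np.random.default_rng(5)
        base = [random_protein(rng, 200) for _ in range(8)]
        proteomes = {
            g: [
                SequenceRecord(id=f"{g}_p{i}", seq=s, alphabet="aa")
                for i, s in enumerate(base)
            ]
            for g in ("A", "B", "C")
        }
        profile = partition_families(
            cluster_proteomes(proteomes), list(proteomes)
        )
        assert profile.n_core == 8
        assert profile.n_accessory == 0
        assert sum(profile.n_unique_per_genome.values()) == 0

    def test_accessory_and_exclusively_absent(self):
        from ppfm.pangenome import GeneFamily

        families = [
            GeneFamily("f1", "x", [("A", "a1"), ("B", "b1")]),  # absent in C
            GeneFamily("f2", "y", [("A", "a2"), ("B", "b2"), ("C", "c2")]),
        ]
        profile = partition_families(families, ["A", "B", "C"])
        assert profile.n_accessory == 1
        assert profile.n_exclusively_absent_per_genome["C"] == 1
        assert profile.n_core == 1


class TestTrees:
    def test_identical_columns_zero_cherry(self):
        import pandas as pd

        df = pd.DataFrame(
            {"A": [1, 1, 0], "B": [1, 1, 0], "C": [0, 1, 1], "D": [1, 0, 1]},
            index=["f1", "f2", "f3"],
        )
        tree = binary_distance_tree(df)
        tips = {t.name: t for t in tree.tips()}
        assert tips["A"].distance(tips["B"]) == 0.0

    def test_single_genome_errors(self):
        import pandas as pd

        df = pd.DataFrame({"A": [1, 0]}, index=["f1", "f2"])
        with pytest.raises(ValueError, match="at least two"):
            binary_distance_tree(df)

    def test_planted_clades_recovered_by_both_trees(self):
        sc = forge_clade_scenario(genomes_per_clade=2, seed=4)
        families = cluster_proteomes(sc.proteomes)
        matrix = pan_matrix(families, sorted(sc.proteomes))
        planted = TreeNode.read(StringIO(sc.planted_newick))
        assert robinson_foulds(binary_distance_tree(matrix), planted) == 0.0
        assert robinson_foulds(core_concat_tree(families, sc.proteomes), planted) == 0.0

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 8])
    def test_nj_exact_on_additive_matrices(self, n_leaves):
        # classic NJ guarantee: additive distances -> generating topology
        rng = np.random.default_rng(n_leaves)
        tree = _random_binary_tree(n_leaves, rng)
        dm = tree.tip_tip_distances()
        recovered = nj_tree(DistanceMatrix(dm.data, dm.ids))
        assert robinson_foulds(recovered, tree) == 0.0

    def test_negative_branches_clamped(self):
        dm = DistanceMatrix(
            np.array(
                [
                    [0.0, 0.1, 0.4, 0.5],
                    [0.1, 0.0, 0.45, 0.55],
                    [0.4, 0.45, 0.0, 0.2],
                    [0.5, 0.55, 0.2, 0.0],
                ]
            ),
            ["a", "b", "c", "d"],
        )
        tree = nj_tree(dm)
        assert all(
            (n.length or 0.0) >= 0.0 for n in tree.traverse() if n.length is not None
        )


def _random_binary_tree(n_leaves, rng):
    """A random resolved topology with positive branch lengths."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    frags = {n: n for n in nodes}
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]  # pop larger index first
        nodes.remove(a)
        nodes.remove(b)
        la, lb = rng.uniform(0.1, 1.0, size=2)
        name = f"({frags[b]}:{lb:.3f},{frags[a]}:{la:.3f})"
        key = f"I{len(frags)}"
        frags[key] = name
        nodes.append(key)
    parts = ",".join(
        f"{frags[n]}:{rng.uniform(0.1, 1.0):.3f}" for n in nodes
    )
    return TreeNode.read(StringIO(f"({parts});"))
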