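"""Pan-genome partitioning and distance trees.

Proteomes are clustered into gene families by greedy centroid clustering at
50% identity (the convention of USEARCH-style pan-genome pipelines):
proteins are processed in order of descending length, and each joins the
first family whose founding representative it matches at or above the
cutoff, else founds its own family. Family identity follows the CD-HIT
convention — identical columns of the best local alignment divided by the
length of the shorter sequence — because raw local-alignment identity is
dominated by short segments on unrelated pairs and is not a usable family
criterion at a 50% cutoff. Families spanning all genomes are the
core genome, families in exactly one genome the unique genome, and the
rest the accessory genome.

Two distance trees are built by neighbor joining: a gene-content tree from
Jaccard distances between binary presence/absence columns, and a core tree
from per-family pairwise protein p-distances averaged across core families
(a deliberate light-weight alternative to multiple-sequence-alignment
concatenation that preserves the tested property, clade recovery).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .align import align_local, global_p_distance
from .io import SequenceRecord


@dataclass
class GeneFamily:
    """A cluster of homologous proteins across genomes."""

    family_id: str
    representative: str  # protein id of the founder
    members: list[tuple[str, str]] = field(default_factory=list)  # (genome, protein)

    @property
    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PanProfile:
    n_core: int
    n_accessory: int
    n_unique_per_genome: dict[str, int]
    n_exclusively_absent_per_genome: dict[str, int]
    pan_total: int

    def __post_init__(self):
        if self.n_core + self.n_accessory + sum(
            self.n_unique_per_genome.values()
        ) != self.pan_total:
            raise ValueError("core + accessory + unique must equal pan total")


def clustering_identity(a: str, b: str) -> float:
    """Family identity: local-alignment identities over the shorter length."""
    summary = align_local(a, b)
    return 100.0 * summary.identities / min(len(a), len(b))


def cluster_proteomes(
    proteomes: dict[str, list[SequenceRecord]], min_identity: float = 50.0
) -> list[GeneFamily]:
    """Greedy centroid clustering of proteomes into gene families.

    Deterministic: proteins are sorted by descending length, then genome
    id, then protein id; each joins the first existing family whose
    representative it matches at >= ``min_identity`` (identical columns of
    the local alignment over the shorter sequence length), else founds a
    new family. Every protein lands in exactly one family.
    """
    if not proteomes or all(not v for v in proteomes.values()):
        raise ValueError("no proteomes to cluster")
    entries = [
        (genome_id, protein)
        for genome_id, prots in proteomes.items()
        for protein in prots
    ]
    entries.sort(key=lambda t: (-len(t[1].seq), t[0], t[1].id))
    families: list[GeneFamily] = []
    reps: list[SequenceRecord] = []
    for genome_id, protein in entries:
        placed = False
        for fam, rep in zip(families, reps):
            if clustering_identity(protein.seq, rep.seq) >= min_identity:
                fam.members.append((genome_id, protein.id))
                placed = True
                break
        if not placed:
            fam = GeneFamily(
                family_id=f"fam{len(families) + 1:05d}",
                representative=protein.id,
                members=[(genome_id, protein.id)],
            )
            families.append(fam)
            reps.append(protein)
    return families


def partition_families(
    families: list[GeneFamily], genome_ids: list[str]
) -> PanProfile:
    """Partition families into core / accessory / unique counts.

    Core families span all genomes; unique families exactly one; the rest
    are accessory. A family spanning all genomes but one increments that
    genome's exclusively-absent count.
    """
    all_genomes = set(genome_ids)
    if not all_genomes:
        raise ValueError("genome_ids is empty")
    n_core = n_accessory = 0
    unique = {g: 0 for g in genome_ids}
    excl_absent = {g: 0 for g in genome_ids}
    for fam in families:
        spanned = fam.genomes
        if spanned == all_genomes:
            n_core += 1
        elif len(spanned) == 1:
            unique[next(iter(spanned))] += 1
        else:
            n_accessory += 1
        if len(spanned) == len(all_genomes) - 1:
            (absent,) = all_genomes - spanned
            excl_absent[absent] += 1
    return PanProfile(
        n_core=n_core,
        n_accessory=n_accessory,
        n_unique_per_genome=unique,
        n_exclusively_absent_per_genome=excl_absent,
        pan_total=len(families),
    )


def pan_matrix(families: list[GeneFamily], genome_ids: list[str]) -> pd.DataFrame:
    """Binary families x genomes presence/absence matrix."""
    df = pd.DataFrame(0, index=[f.family_id for f in families], columns=genome_ids, dtype=int)
    for fam in families:
        for g in fam.genomes:
            df.loc[fam.family_id, g] = 1
    return df


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree with negative branch lengths clamped to 0."""
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def binary_distance_tree(matrix, metric: str = "jaccard") -> TreeNode:
    """NJ tree from a binary presence/absence matrix (features x genomes).

    Accepts a plain DataFrame or any object with a ``df`` attribute (e.g. a
    screening PresenceMatrix). Jaccard distance is the default (robust to
    genome-size imbalance); ``metric="hamming"`` uses the simple matching
    distance instead.
    """
    df = getattr(matrix, "df", matrix)
    genomes = list(df.columns)
    if len(genomes) < 2:
        raise ValueError("a tree needs at least two genomes")
    X = df.to_numpy(dtype=bool).T  # genomes x features
    n = len(genomes)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "jaccard":
                union = np.logical_or(X[i], X[j]).sum()
                inter = np.logical_and(X[i], X[j]).sum()
                d = 0.0 if union == 0 else 1.0 - inter / union
            elif metric == "hamming":
                d = np.mean(X[i] != X[j])
            else:
                raise ValueError(f"unknown metric {metric!r}")
            D[i, j] = D[j, i] = d
    return nj_tree(DistanceMatrix(D, genomes))


def core_concat_tree(
    families: list[GeneFamily],
    proteomes: dict[str, list[SequenceRecord]],
) -> TreeNode:
    """NJ tree from core-family protein distances averaged over families.

    For each core family, one member per genome (the first by protein id)
    is compared to every other genome's member by global-alignment
    p-distance; the per-family genome x genome matrices are averaged and
    the mean matrix is handed to neighbor joining.
    """
    genomes = sorted(proteomes)
    if len(genomes) < 2:
        raise ValueError("a tree needs at least two genomes")
    seq_by_id = {
        p.id: p.seq for prots in proteomes.values() for p in prots
    }
    core = [f for f in families if f.genomes == set(genomes)]
    if not core:
        raise ValueError("no core families to build a tree from")
    n = len(genomes)
    total = np.zeros((n, n))
    for fam in core:
        member = {}
        for g, pid in sorted(fam.members, key=lambda t: t[1]):
            member.setdefault(g, pid)
        for i in range(n):
            for j in range(i + 1, n):
                d = global_p_distance(
                    seq_by_id[member[genomes[i]]], seq_by_id[member[genomes[j]]]
                )
                total[i, j] += d
                total[j, i] += d
    return nj_tree(DistanceMatrix(total / len(core), genomes))


def robinson_foulds(a: TreeNode, b: TreeNode) -> float:
    """Robinson–Foulds topological distance between two trees."""
    return float(a.compare_rfd(b))


def families_table(families: list[GeneFamily]) -> pd.DataFrame:
    rows = [
        {
            "family_id": f.family_id,
            "representative": f.representative,
            "genome_id": g,
            "protein_id": p,
        }
        for f in families
        for g, p in f.members
    ]
    return pd.DataFrame(rows)
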