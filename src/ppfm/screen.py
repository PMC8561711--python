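"""Reference-protein presence/absence screening and cluster conservation.

Implements the ortholog screen used throughout the pipeline: each reference
protein is searched against a genome's proteome by local alignment, hits
below 50% identity or above e-value 0.001 are discarded, and per genome only
the hit with the highest identity is kept. Per-cluster completeness follows
the strict >75% conservation rule, and a genomic-context check verifies that
an anchor gene (e.g. xoxF) co-occurs with its partners (xoxG, xoxJ) within a
bounded number of intervening genes on the same replicon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .align import KA_K, KA_LAMBDA, align_local, evalue
from .io import Genome, SequenceRecord, read_fasta


@dataclass(frozen=True)
class ClusterGene:
    name: str
    protein: SequenceRecord
    essential: bool = False


@dataclass(frozen=True)
class ReferenceCluster:
    """An ordered reference gene set, the unit of conservation scoring."""

    name: str
    genes: tuple[ClusterGene, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"cluster {self.name!r} has no genes")
        names = [g.name for g in self.genes]
        if len(names) != len(set(names)):
            raise ValueError(f"cluster {self.name!r} has duplicate gene names")

    def __len__(self) -> int:
        return len(self.genes)

    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]


@dataclass(frozen=True)
class HitRecord:
    """One retained query-vs-genome hit (best per query per genome)."""

    query_gene: str
    target_gene_id: str
    identity: float
    evalue: float
    bitscore: float
    aligned_columns: int = 0


@dataclass
class PresenceMatrix:
    """Binary genes-or-clusters x genomes matrix with hit provenance."""

    df: pd.DataFrame  # rows: query names, cols: genome ids, cells {0,1}
    provenance: dict[tuple[str, str], HitRecord] = field(default_factory=dict)

    def __post_init__(self):
        if not self.df.isin([0, 1]).all().all():
            raise ValueError("presence matrix cells must be binary")
        for (row, col) in self.provenance:
            if self.df.loc[row, col] != 1:
                raise ValueError(f"provenance for a 0-cell: ({row}, {col})")


def load_clusters(config_path: str | Path) -> list[ReferenceCluster]:
    """Load reference clusters from a YAML config plus protein FASTA files.

    Layout::

        clusters:
          - name: mxa
            fasta: mxa.faa          # relative to the YAML file
            genes: [{name: mxaF, essential: true}, {name: mxaJ}, ...]

    Each gene name must match a FASTA record id.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    clusters = []
    for entry in cfg["clusters"]:
        records = {
            r.id: r for r in read_fasta(config_path.parent / entry["fasta"], "aa")
        }
        genes = []
        for g in entry["genes"]:
            if g["name"] not in records:
                raise ValueError(
                    f"cluster {entry['name']!r}: no FASTA record for gene {g['name']!r}"
                )
            genes.append(
                ClusterGene(
                    name=g["name"],
                    protein=records[g["name"]],
                    essential=bool(g.get("essential", False)),
                )
            )
        clusters.append(ReferenceCluster(name=entry["name"], genes=tuple(genes)))
    return clusters


def _bitscore(raw: float, lam: float = KA_LAMBDA, k: float = KA_K) -> float:
    import math

    return (lam * raw - math.log(k)) / math.log(2)


def protein_identity_search(
    queries: Sequence[SequenceRecord],
    proteome: Sequence[SequenceRecord],
    min_identity: float = 50.0,
    max_evalue: float = 1e-3,
    identity_over: str = "alignment",
) -> list[HitRecord]:
    """Local-alignment screen of reference proteins against one proteome.

    Every query is aligned against every proteome member (Smith–Waterman,
    BLOSUM62). Pairs with identity >= ``min_identity`` and e-value <=
    ``max_evalue`` are retained; duplicates are then removed so that only
    the hit with the highest identity survives per query. Ties break to the
    longer alignment, then the lexicographically smaller target id.

    ``identity_over`` selects the denominator of the identity fraction:
    ``"alignment"`` (identical columns / aligned columns, the BLAST
    convention and the default) or ``"query"`` (identical columns / aligned
    query residues).
    """
    if not queries or not proteome:
        raise ValueError("queries and proteome must be nonempty")
    if identity_over not in ("alignment", "query"):
        raise ValueError("identity_over must be 'alignment' or 'query'")
    db_len = sum(len(p) for p in proteome)
    hits: list[HitRecord] = []
    for query in queries:
        best: HitRecord | None = None
        for target in proteome:
            summary = align_local(query.seq, target.seq)
            ident = (
                summary.identity_pct
                if identity_over == "alignment"
                else summary.identity_pct_query
            )
            e = evalue(summary.score, len(query), db_len)
            if ident < min_identity or e > max_evalue:
                continue
            hit = HitRecord(
                query_gene=query.id,
                target_gene_id=target.id,
                identity=ident,
                evalue=e,
                bitscore=_bitscore(summary.score),
                aligned_columns=summary.columns,
            )
            if best is None or _hit_key(hit) > _hit_key(best):
                best = hit
        if best is not None:
            hits.append(best)
    return hits


def _hit_key(h: HitRecord):
    # higher identity, then longer alignment, then smaller target id
    return (h.identity, h.aligned_columns, _NegStr(h.target_gene_id))


class _NegStr(str):
    """String whose ordering is reversed, for descending-sort tie-breaks."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def presence_absence(
    clusters: Sequence[ReferenceCluster],
    genomes: Sequence[Genome],
    min_identity: float = 50.0,
    max_evalue: float = 1e-3,
) -> PresenceMatrix:
    """Screen every cluster gene against every genome.

    Rows are ``cluster:gene`` names; a cell is 1 iff the screen retains a
    hit, with the retained :class:`HitRecord` stored as provenance.
    """
    rows = [f"{c.name}:{g.name}" for c in clusters for g in c.genes]
    queries_by_row = {
        f"{c.name}:{g.name}": SequenceRecord(
            id=f"{c.name}:{g.name}", seq=g.protein.seq, alphabet="aa"
        )
        for c in clusters
        for g in c.genes
    }
    df = pd.DataFrame(
        0, index=rows, columns=[g.genome_id for g in genomes], dtype=int
    )
    provenance: dict[tuple[str, str], HitRecord] = {}
    for genome in genomes:
        proteome = genome.proteome()
        if not proteome:
            continue
        retained = protein_identity_search(
            list(queries_by_row.values()), proteome, min_identity, max_evalue
        )
        for hit in retained:
            df.loc[hit.query_gene, genome.genome_id] = 1
            provenance[(hit.query_gene, genome.genome_id)] = hit
    return PresenceMatrix(df=df, provenance=provenance)


def cluster_completeness(
    cluster: ReferenceCluster,
    column: Mapping[str, int] | Sequence[int],
    conserved_above: float = 75.0,
    require_essential: bool = False,
) -> tuple[float, bool]:
    """Percent of cluster genes present and the conservation call.

    A cluster is conserved when *more than* ``conserved_above`` percent of
    its genes are present (strict inequality: 3 of 4 = 75.0% is not
    conserved). With ``require_essential`` the call additionally demands
    every essential gene be present.
    """
    if isinstance(column, Mapping):
        cells = [int(bool(column.get(g.name, 0))) for g in cluster.genes]
    else:
        cells = [int(bool(c)) for c in column]
        if len(cells) != len(cluster):
            raise ValueError("column length does not match cluster size")
    percent = 100.0 * sum(cells) / len(cluster)
    conserved = percent > conserved_above
    if require_essential:
        present = {
            g.name for g, c in zip(cluster.genes, cells) if c
        }
        conserved = conserved and all(
            g.name in present for g in cluster.genes if g.essential
        )
    return percent, conserved


def context_check(
    anchor_hit: HitRecord,
    partner_hits: Iterable[HitRecord],
    genome: Genome,
    max_intervening: int = 5,
) -> bool:
    """Is the anchor gene co-clustered with all of its partner genes?

    True iff every partner has a retained hit on the anchor's replicon with
    at most ``max_intervening`` genes (by rank) between them. Used to test
    whether a xoxF copy sits in its functional xoxF–xoxG–xoxJ cluster.
    """
    anchor_gene = genome.gene(anchor_hit.target_gene_id)
    if anchor_gene.rank is None:
        raise ValueError(f"anchor gene {anchor_gene.gene_id!r} lacks a rank")
    partners = list(partner_hits)
    if not partners:
        return True
    by_query: dict[str, list[HitRecord]] = {}
    for h in partners:
        by_query.setdefault(h.query_gene, []).append(h)
    for query, hits_for_query in by_query.items():
        ok = False
        for h in hits_for_query:
            try:
                g = genome.gene(h.target_gene_id)
            except KeyError:
                continue
            if g.replicon_id != anchor_gene.replicon_id or g.rank is None:
                continue
            if abs(g.rank - anchor_gene.rank) - 1 <= max_intervening:
                ok = True
                break
        if not ok:
            return False
    return True


def completeness_report(
    clusters: Sequence[ReferenceCluster],
    matrix: PresenceMatrix,
    conserved_above: float = 75.0,
) -> pd.DataFrame:
    """Per-cluster completeness (%) and conservation calls per genome."""
    records = []
    for cluster in clusters:
        for genome_id in matrix.df.columns:
            column = {
                g.name: int(matrix.df.loc[f"{cluster.name}:{g.name}", genome_id])
                for g in cluster.genes
            }
            pct, conserved = cluster_completeness(cluster, column, conserved_above)
            records.append(
                {
                    "cluster": cluster.name,
                    "genome": genome_id,
                    "completeness_pct": pct,
                    "conserved": conserved,
                }
            )
    return pd.DataFrame(records)
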