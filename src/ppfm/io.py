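"""Readers/writers for the formats the pipeline touches, plus assembly QC.

Sequences are FASTA (nucleotide or amino acid), gene models are GFF3 CDS
rows, tabular data is TSV. Coordinates are 1-based inclusive throughout
(GFF3 convention); algorithms convert to half-open internally and never
leak that convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

_NT_CHARS = set("ACGTURYSWKMBDHVN")
_AA_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence, nucleotide (``nt``) or amino acid (``aa``)."""

    id: str
    seq: str
    description: str = ""
    alphabet: str = "nt"

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence record requires a nonempty id")
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        valid = _NT_CHARS if self.alphabet == "nt" else _AA_CHARS
        bad = set(self.seq) - valid
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid {self.alphabet} characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneRecord:
    """A CDS gene model: 1-based inclusive coordinates on a replicon.

    ``rank`` is the ordinal index of the gene along its replicon when genes
    are sorted by ascending start; it is strand-agnostic and is the unit of
    the genomic-context (co-clustering) checks.
    """

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    rank: int | None = None

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Genome:
    """An annotated assembly: replicon sequences, gene models, proteome.

    The unit of every comparison in the pipeline. ``proteins`` maps
    ``gene_id`` to the translated product.
    """

    genome_id: str
    replicons: dict[str, SequenceRecord]
    genes: list[GeneRecord] = field(default_factory=list)
    proteins: dict[str, SequenceRecord] = field(default_factory=dict)

    def __post_init__(self):
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"genome {self.genome_id!r}: duplicate gene ids")

    @property
    def size_bp(self) -> int:
        return sum(len(r) for r in self.replicons.values())

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def proteome(self) -> list[SequenceRecord]:
        return list(self.proteins.values())


@dataclass(frozen=True)
class AssemblyStats:
    genome_id: str
    completeness: float
    contamination: float
    gc: float = 0.0
    size_bp: int = 1
    cds_count: int = 0

    def __post_init__(self):
        for name in ("completeness", "contamination", "gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} out of [0, 100]: {v}")
        if self.size_bp <= 0:
            raise ValueError("size_bp must be positive")


@dataclass(frozen=True)
class QCPartition:
    passed: tuple[AssemblyStats, ...]
    failed: tuple[AssemblyStats, ...]


def read_fasta(path: str | Path, alphabet: str = "nt") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Order is preserved and sequences are uppercased (softmasking carries no
    information for identity statistics). Duplicate ids and empty sequences
    are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA record {rec.id!r} in {path}")
        records.append(
            SequenceRecord(
                id=rec.id, seq=seq, description=rec.description, alphabet=alphabet
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().rstrip(";").split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff_genes(path: str | Path) -> list[GeneRecord]:
    """Extract CDS rows from a GFF3 file as :class:`GeneRecord` objects.

    Only ``CDS`` features are consumed. Ranks are assigned per replicon by
    ascending start. A CDS without an ``ID`` attribute, or with ``end`` <
    ``start``, is an error.
    """
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"{path}:{lineno}: CDS end < start")
            attributes = _parse_gff_attributes(attrs)
            if "ID" not in attributes:
                raise ValueError(f"{path}:{lineno}: CDS row lacks an ID attribute")
            genes.append(
                GeneRecord(
                    gene_id=attributes["ID"],
                    replicon_id=seqid,
                    start=start_i,
                    end=end_i,
                    strand=strand,
                    product=attributes.get("product", ""),
                )
            )
    ids = [g.gene_id for g in genes]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate CDS ID attributes {dup}")
    return assign_ranks(genes)


def write_gff_genes(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.replicon_id}\tppfm\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
            )


def assign_ranks(genes: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Return genes sorted by (replicon, start) with per-replicon 1-based ranks."""
    ordered = sorted(genes, key=lambda g: (g.replicon_id, g.start, g.gene_id))
    out: list[GeneRecord] = []
    counter: dict[str, int] = {}
    for g in ordered:
        counter[g.replicon_id] = counter.get(g.replicon_id, 0) + 1
        out.append(dataclasses.replace(g, rank=counter[g.replicon_id]))
    return out


def qc_filter(
    stats: Iterable[AssemblyStats],
    min_completeness: float = 90.0,
    max_contamination: float = 5.0,
) -> QCPartition:
    """Partition assemblies by the standard QC rule.

    An assembly passes iff completeness > 90 and contamination < 5, both
    strict. The partition is exhaustive and disjoint.
    """
    passed, failed = [], []
    for s in stats:
        if s.completeness > min_completeness and s.contamination < max_contamination:
            passed.append(s)
        else:
            failed.append(s)
    return QCPartition(passed=tuple(passed), failed=tuple(failed))


def read_assembly_stats(path: str | Path) -> list[AssemblyStats]:
    df = pd.read_csv(path, sep="\t")
    cols = {f.name for f in dataclasses.fields(AssemblyStats)}
    return [
        AssemblyStats(**{k: v for k, v in row.items() if k in cols})
        for row in df.to_dict("records")
    ]


def write_assembly_stats(stats: Iterable[AssemblyStats], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in stats]).to_csv(
        path, sep="\t", index=False
    )
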