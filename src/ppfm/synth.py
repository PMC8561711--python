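"""Synthetic genomes with known ground truth.

Every downstream stage of the pipeline is exercised on genomes forged here:
multi-replicon assemblies with CDS annotations and translated proteomes,
genome pairs at a controlled substitution divergence, gene clusters planted
at a controlled completeness, and alcohol-dehydrogenase protein families
with planted active-site residues. Each forging operation returns the truth
(realized divergence, implanted gene ids, planted residues) alongside the
artifact, so recovery by the analysis stages can be scored exactly.

Generators emulate the shape of real methylotroph assemblies (one or a few
replicons, high GC, dense CDS annotation) at reduced scale. Substitutions
are uniform over sites with a 2:1 transition:transversion ratio; the
identity statistics downstream depend only on the mismatch proportion, not
on the substitution spectrum. Coding frames are protected: a substitution
that would create an in-frame stop codon is redrawn to a different
substitution at the same site, and indels are confined to intergenic
sequence, so nucleotide- and protein-level screens stay mutually
consistent. All operations are deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .io import GeneRecord, Genome, SequenceRecord, assign_ranks
from .screen import ReferenceCluster

_STOPS = frozenset(standard_dna_table.stop_codons)
_SENSE_CODONS = sorted(standard_dna_table.forward_table)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# aa -> synonymous codons, for back-translation
_CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS_FOR_AA.setdefault(_aa, []).append(_codon)
for _v in _CODONS_FOR_AA.values():
    _v.sort()

_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate(coding: str) -> str:
    aa = str(Seq(coding).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa.replace("*", "X")  # internal stops (post-divergence) masked


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one forged genome."""

    n_replicons: int
    replicon_lengths: tuple[int, ...]
    n_genes: int
    gene_length_range: tuple[int, int] = (300, 1200)
    gc_target: float = 66.0
    seed: int = 0

    def __post_init__(self):
        if len(self.replicon_lengths) != self.n_replicons:
            raise ValueError("replicon_lengths length must equal n_replicons")
        if not 0.0 < self.gc_target < 100.0:
            raise ValueError("gc_target must be in (0, 100)")
        lo, hi = self.gene_length_range
        if not 9 <= lo <= hi:
            raise ValueError("gene_length_range must satisfy 9 <= lo <= hi")


@dataclass(frozen=True)
class DivergenceSpec:
    """Substitution proportion and indel rate applied to a genome."""

    subst_proportion: float
    indel_rate: float = 0.0  # events per kb, intergenic only
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.subst_proportion < 0.75:
            raise ValueError("subst_proportion must be in [0, 0.75)")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")


@dataclass(frozen=True)
class PlantSpec:
    """Which fraction of a reference cluster to implant, and how."""

    cluster: ReferenceCluster
    completeness_fraction: float = 1.0
    contiguous: bool = True
    intervening_genes: int = 0

    def __post_init__(self):
        if not 0.0 <= self.completeness_fraction <= 1.0:
            raise ValueError("completeness_fraction must be in [0, 1]")
        if self.intervening_genes < 0:
            raise ValueError("intervening_genes must be >= 0")


@dataclass(frozen=True)
class DivergenceResult:
    genome: Genome
    realized_p: float  #: measured mismatch fraction before indels
    n_substitutions: int
    n_indels: int


@dataclass(frozen=True)
class ImplantedGene:
    gene_name: str
    gene_id: str
    replicon_id: str


@dataclass(frozen=True)
class ImplantResult:
    genome: Genome
    implanted: tuple[ImplantedGene, ...]

    @property
    def implanted_gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.implanted]


@dataclass(frozen=True)
class AdhFamilyResult:
    records: tuple[SequenceRecord, ...]
    #: per record id: the residue actually planted at each override position
    planted_residues: dict[str, dict[int, str]] = field(default_factory=dict)
    realized_divergence: dict[str, float] = field(default_factory=dict)


def _codon_probs(gc_target: float) -> np.ndarray:
    """Probabilities over the 61 sense codons from per-base GC weighting."""
    g = gc_target / 100.0
    base_p = {"A": (1 - g) / 2, "T": (1 - g) / 2, "G": g / 2, "C": g / 2}
    w = np.array(
        [base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in _SENSE_CODONS]
    )
    return w / w.sum()


def _random_coding(rng: np.random.Generator, length: int, codon_p: np.ndarray) -> str:
    """A coding sequence of ``length`` bp (multiple of 3): ATG...stop."""
    n_codons = length // 3
    body = rng.choice(len(_SENSE_CODONS), size=max(n_codons - 2, 1), p=codon_p)
    stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + stop


def forge_genome(spec: GenomeSpec, genome_id: str = "genome") -> Genome:
    """Forge an annotated genome matching ``spec``.

    Genes are placed without overlap, separated by random intergenic gaps;
    intergenic base composition is solved per replicon so the realized GC
    tracks ``gc_target`` (within one point for replicons >= 50 kb). Every
    gene carries a translated protein with no internal stop codons.
    """
    rng = np.random.default_rng(spec.seed)
    codon_p = _codon_probs(spec.gc_target)
    total_len = sum(spec.replicon_lengths)
    # apportion genes to replicons by length (largest remainder)
    quotas = [spec.n_genes * L / total_len for L in spec.replicon_lengths]
    counts = [int(q) for q in quotas]
    for _ in range(spec.n_genes - sum(counts)):
        i = int(np.argmax([q - c for q, c in zip(quotas, counts)]))
        counts[i] += 1

    min_gap = 20
    replicons: dict[str, SequenceRecord] = {}
    genes: list[GeneRecord] = []
    proteins: dict[str, SequenceRecord] = {}
    gene_idx = 0
    for rep_i, (rep_len, n_genes_rep) in enumerate(
        zip(spec.replicon_lengths, counts)
    ):
        rep_id = f"{genome_id}_rep{rep_i + 1}"
        lo, hi = spec.gene_length_range
        lens = rng.integers(lo, hi + 1, size=n_genes_rep)
        lens = np.maximum((lens // 3) * 3, 9)
        footprint = int(lens.sum())
        slack = rep_len - footprint - min_gap * (n_genes_rep + 1)
        if slack < 0:
            raise ValueError(
                f"genes cannot be placed: replicon {rep_id} needs "
                f"{footprint + min_gap * (n_genes_rep + 1)} bp, has {rep_len}"
            )
        extra = (
            rng.multinomial(slack, np.full(n_genes_rep + 1, 1 / (n_genes_rep + 1)))
            if n_genes_rep >= 0 and slack > 0
            else np.zeros(n_genes_rep + 1, dtype=int)
        )
        gaps = extra + min_gap

        parts: list[str] = []
        gene_gc = 0
        pos = 0  # 0-based running coordinate
        gene_entries = []  # (gene_id, start, end, strand, coding)
        for j in range(n_genes_rep):
            pos += int(gaps[j])
            parts.append(("GAP", int(gaps[j])))  # placeholder, filled later
            coding = _random_coding(rng, int(lens[j]), codon_p)
            strand = "+" if rng.random() < 0.5 else "-"
            placed = coding if strand == "+" else _revcomp(coding)
            gene_id = f"{genome_id}_g{gene_idx + 1:05d}"
            gene_idx += 1
            gene_entries.append((gene_id, pos + 1, pos + len(placed), strand, coding))
            parts.append(placed)
            gene_gc += placed.count("G") + placed.count("C")
            pos += len(placed)
        parts.append(("GAP", int(gaps[-1] if n_genes_rep > 0 else rep_len)))

        # intergenic composition solved by exact count so the replicon GC
        # hits gc_target up to rounding (genes dominate the fluctuation
        # otherwise)
        bg_len = rep_len - footprint
        n_gc = int(round(spec.gc_target / 100.0 * rep_len - gene_gc))
        n_gc = min(max(n_gc, 0), bg_len)
        strong = rng.choice(list("GC"), size=n_gc)
        weak = rng.choice(list("AT"), size=bg_len - n_gc)
        pool = np.concatenate([strong, weak])
        rng.shuffle(pool)
        consumed = 0
        seq_parts = []
        for part in parts:
            if isinstance(part, tuple):
                n = part[1]
                seq_parts.append("".join(pool[consumed : consumed + n]))
                consumed += n
            else:
                seq_parts.append(part)
        replicons[rep_id] = SequenceRecord(
            id=rep_id, seq="".join(seq_parts), alphabet="nt"
        )
        for gene_id, start, end, strand, coding in gene_entries:
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    replicon_id=rep_id,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
            proteins[gene_id] = SequenceRecord(
                id=gene_id, seq=_translate(coding), alphabet="aa"
            )
    return Genome(
        genome_id=genome_id,
        replicons=replicons,
        genes=assign_ranks(genes),
        proteins=proteins,
    )


# substitution lookup: transition partner and the two transversion partners
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _coding_seq(rep_seq: str, gene: GeneRecord) -> str:
    s = rep_seq[gene.start - 1 : gene.end]
    return s if gene.strand == "+" else _revcomp(s)


def diverge_genome(
    genome: Genome, spec: DivergenceSpec, genome_id: str | None = None
) -> DivergenceResult:
    """Apply substitutions (and optionally intergenic indels) to a genome.

    Exactly ``round(p * L)`` sites per replicon are substituted, every one
    to a different base (transition:transversion 2:1), so the realized
    mismatch fraction before indels equals ``p`` up to rounding. A
    substitution that would create an in-frame stop codon inside a gene is
    redrawn to a different base at the same site. Indels (geometric
    lengths, mean 3 bp) fall only in intergenic sequence; gene coordinates
    are remapped through them. Proteins are re-derived from the mutated
    nucleotide sequence.
    """
    rng = np.random.default_rng(spec.seed)
    genome_id = genome_id or f"{genome.genome_id}_div"
    new_replicons: dict[str, SequenceRecord] = {}
    new_genes: list[GeneRecord] = []
    total_sub = 0
    total_indel = 0
    total_len = 0
    for rep_id, rep in genome.replicons.items():
        seq = list(rep.seq)
        L = len(seq)
        total_len += L
        n_sub = int(round(spec.subst_proportion * L))
        sites = rng.choice(L, size=n_sub, replace=False) if n_sub else np.array([], int)
        r = rng.random(n_sub)
        for site, u in zip(sites, r):
            old = seq[site]
            if u < 0.5:
                seq[site] = _TRANSITION[old]
            else:
                seq[site] = _TRANSVERSIONS[old][0 if u < 0.75 else 1]
        total_sub += n_sub

        rep_genes = [g for g in genome.genes if g.replicon_id == rep_id]
        mutated = "".join(seq)
        original = rep.seq
        for gene in rep_genes:
            coding = _coding_seq(mutated, gene)
            coding_orig = _coding_seq(original, gene)
            fixed = _fix_internal_stops(coding, coding_orig)
            if fixed != coding:
                # write the repaired coding sequence back into the replicon
                placed = fixed if gene.strand == "+" else _revcomp(fixed)
                seq[gene.start - 1 : gene.end] = list(placed)
        mutated = "".join(seq)

        if spec.indel_rate > 0:
            mutated, rep_genes, n_ev = _apply_intergenic_indels(
                mutated, rep_genes, spec.indel_rate, rng
            )
            total_indel += n_ev
        new_rep_id = rep_id
        new_replicons[new_rep_id] = SequenceRecord(
            id=new_rep_id, seq=mutated, alphabet="nt"
        )
        new_genes.extend(rep_genes)

    new_genes = assign_ranks(new_genes)
    proteins = {
        g.gene_id: SequenceRecord(
            id=g.gene_id,
            seq=_translate(_coding_seq(new_replicons[g.replicon_id].seq, g)),
            alphabet="aa",
        )
        for g in new_genes
    }
    out = Genome(
        genome_id=genome_id,
        replicons=new_replicons,
        genes=new_genes,
        proteins=proteins,
    )
    return DivergenceResult(
        genome=out,
        realized_p=total_sub / total_len if total_len else 0.0,
        n_substitutions=total_sub,
        n_indels=total_indel,
    )


def _fix_internal_stops(coding: str, coding_orig: str) -> str:
    """Redraw mutated bases that created in-frame internal stop codons.

    The replacement stays a substitution relative to the original base, so
    the realized mismatch count is unchanged. Among the three stop codons
    no single-base neighborhood is all-stop, so a fix always exists.
    """
    out = list(coding)
    n_codons = len(coding) // 3
    for ci in range(n_codons - 1):  # exclude the terminal stop
        codon = "".join(out[3 * ci : 3 * ci + 3])
        if codon not in _STOPS:
            continue
        fixed = False
        for k in range(3):
            p = 3 * ci + k
            orig = coding_orig[p]
            if out[p] == orig:
                continue  # not a mutated site; keep substitution accounting
            for b in "ACGT":
                if b == orig or b == out[p]:
                    continue
                trial = codon[:k] + b + codon[k + 1 :]
                if trial not in _STOPS:
                    out[p] = b
                    codon = trial
                    fixed = True
                    break
            if fixed:
                break
        if not fixed:  # pragma: no cover - unreachable by construction
            raise AssertionError("in-frame stop could not be repaired")
    return "".join(out)


def _apply_intergenic_indels(seq, genes, rate_per_kb, rng):
    """Insert/delete short stretches in intergenic space; remap gene coords."""
    L = len(seq)
    n_events = int(rng.poisson(rate_per_kb * L / 1000.0))
    if n_events == 0:
        return seq, genes, 0
    # intergenic intervals, 0-based half-open
    bounds = sorted((g.start - 1, g.end) for g in genes)
    gaps = []
    prev = 0
    for s, e in bounds:
        if s > prev:
            gaps.append((prev, s))
        prev = max(prev, e)
    if prev < L:
        gaps.append((prev, L))
    if not gaps:
        return seq, genes, 0
    gap_lens = np.array([e - s for s, e in gaps], dtype=float)
    events = []  # (pos, delta, payload)
    for _ in range(n_events):
        gi = rng.choice(len(gaps), p=gap_lens / gap_lens.sum())
        s, e = gaps[gi]
        pos = int(rng.integers(s, e))
        length = int(rng.geometric(1.0 / 3.0))
        if rng.random() < 0.5:
            payload = "".join(rng.choice(list("ACGT"), size=length))
            events.append((pos, length, payload))
        else:
            length = min(length, e - pos)  # deletions stay intergenic
            events.append((pos, -length, None))
    events.sort(key=lambda t: t[0], reverse=True)
    chars = list(seq)
    for pos, delta, payload in events:
        if delta > 0:
            chars[pos:pos] = list(payload)
        else:
            del chars[pos : pos - delta]
    import dataclasses as _dc

    new_genes = []
    for g in genes:
        shift = sum(d for p, d, _ in events if p < g.start - 1)
        new_genes.append(
            _dc.replace(g, start=g.start + shift, end=g.end + shift, rank=None)
        )
    return "".join(chars), new_genes, n_events


def backtranslate(protein: str, rng: np.random.Generator) -> str:
    """A coding sequence (with stop codon) translating to ``protein``."""
    codons = []
    for aa in protein:
        options = _CODONS_FOR_AA.get(aa)
        if options is None:  # X or other ambiguity: any sense codon
            options = _CODONS_FOR_AA["L"]
        codons.append(options[rng.integers(len(options))])
    codons.append(["TAA", "TAG", "TGA"][rng.integers(3)])
    return "".join(codons)


def implant_cluster(
    genome: Genome, plant: PlantSpec, seed: int = 0, genome_id: str | None = None
) -> ImplantResult:
    """Insert a controlled fraction of a reference cluster into a genome.

    Exactly ``round(completeness_fraction * cluster size)`` genes are
    implanted — the first so many in cluster order, deterministically. With
    ``contiguous`` they occupy consecutive ranks, separated by
    ``intervening_genes`` forged filler genes each; otherwise they scatter
    over distinct intergenic gaps. A fraction yielding zero genes warns and
    returns the genome unchanged. The returned truth lists every implanted
    gene id.
    """
    rng = np.random.default_rng(seed)
    cluster = plant.cluster
    n_implant = int(round(plant.completeness_fraction * len(cluster)))
    genome_id = genome_id or genome.genome_id
    if n_implant == 0:
        warnings.warn(
            f"completeness_fraction {plant.completeness_fraction} of cluster "
            f"{cluster.name!r} yields 0 genes; genome unchanged"
        )
        return ImplantResult(genome=genome, implanted=())
    chosen = cluster.genes[:n_implant]

    rep_id = max(genome.replicons, key=lambda r: len(genome.replicons[r]))
    rep_seq = genome.replicons[rep_id].seq
    rep_genes = sorted(
        (g for g in genome.genes if g.replicon_id == rep_id), key=lambda g: g.start
    )
    other_genes = [g for g in genome.genes if g.replicon_id != rep_id]

    # candidate insertion boundaries: midpoints of intergenic gaps (0-based)
    boundaries = [0] + [g.end for g in rep_genes] + [len(rep_seq)]
    gap_points = []
    for i in range(len(boundaries) - 1):
        lo = boundaries[i]
        hi = rep_genes[i].start - 1 if i < len(rep_genes) else len(rep_seq)
        if hi > lo:
            gap_points.append((lo + hi) // 2)
    if not gap_points:
        raise ValueError("no intergenic space to implant into")

    codon_p = _codon_probs(50.0)
    spacer = lambda: "".join(rng.choice(list("ACGT"), size=30))  # noqa: E731

    def _segment_for(gene_list):
        """Build (sequence, [(name_or_None, offset, length, coding)])."""
        seq_parts, entries, off = [], [], 0
        for i, cg in enumerate(gene_list):
            sp = spacer()
            seq_parts.append(sp)
            off += len(sp)
            coding = backtranslate(cg.protein.seq, rng)
            entries.append((cg.name, off, len(coding), coding))
            seq_parts.append(coding)
            off += len(coding)
            if plant.intervening_genes and i < len(gene_list) - 1:
                for _ in range(plant.intervening_genes):
                    sp = spacer()
                    seq_parts.append(sp)
                    off += len(sp)
                    filler = _random_coding(rng, 300, codon_p)
                    entries.append((None, off, len(filler), filler))
                    seq_parts.append(filler)
                    off += len(filler)
        sp = spacer()
        seq_parts.append(sp)
        off += len(sp)
        return "".join(seq_parts), entries

    if plant.contiguous:
        insertions = [(int(rng.choice(gap_points)), list(chosen))]
    else:
        points = rng.choice(
            len(gap_points), size=min(n_implant, len(gap_points)), replace=False
        )
        insertions = [
            (gap_points[int(pi)], [cg]) for pi, cg in zip(points, chosen)
        ]
        if len(insertions) < n_implant:
            raise ValueError("not enough intergenic gaps for scattered implant")
    insertions.sort(key=lambda t: t[0], reverse=True)

    import dataclasses as _dc

    chars = rep_seq
    new_gene_records: list[GeneRecord] = []
    new_proteins: dict[str, SequenceRecord] = dict(genome.proteins)
    implanted: list[ImplantedGene] = []
    shifted = {g.gene_id: g for g in rep_genes}
    filler_idx = 0
    for point, gene_list in insertions:
        segment, entries = _segment_for(gene_list)
        chars = chars[:point] + segment + chars[point:]
        for gid, g in list(shifted.items()):
            if g.start - 1 >= point:
                shifted[gid] = _dc.replace(
                    g, start=g.start + len(segment), end=g.end + len(segment)
                )
        # genes from earlier (larger-coordinate) insertions shift as well
        for i, prior in enumerate(new_gene_records):
            if prior.start - 1 >= point:
                new_gene_records[i] = _dc.replace(
                    prior,
                    start=prior.start + len(segment),
                    end=prior.end + len(segment),
                )
        for name, off, length, coding in entries:
            if name is not None:
                gene_id = f"{genome_id}_{cluster.name}_{name}"
                implanted.append(
                    ImplantedGene(gene_name=name, gene_id=gene_id, replicon_id=rep_id)
                )
            else:
                filler_idx += 1
                gene_id = f"{genome_id}_{cluster.name}_filler{filler_idx}"
            new_gene_records.append(
                GeneRecord(
                    gene_id=gene_id,
                    replicon_id=rep_id,
                    start=point + off + 1,
                    end=point + off + length,
                    strand="+",
                )
            )
            new_proteins[gene_id] = SequenceRecord(
                id=gene_id, seq=_translate(coding), alphabet="aa"
            )

    all_genes = assign_ranks(
        list(shifted.values()) + new_gene_records + other_genes
    )
    replicons = dict(genome.replicons)
    replicons[rep_id] = SequenceRecord(id=rep_id, seq=chars, alphabet="nt")
    out = Genome(
        genome_id=genome_id,
        replicons=replicons,
        genes=all_genes,
        proteins=new_proteins,
    )
    return ImplantResult(genome=out, implanted=tuple(implanted))


def mutate_protein(
    seq: str, divergence: float, rng: np.random.Generator
) -> str:
    """Substitute ``round(divergence * len)`` positions to different residues."""
    n_mut = int(round(divergence * len(seq)))
    if n_mut == 0:
        return seq
    out = list(seq)
    sites = rng.choice(len(seq), size=n_mut, replace=False)
    for site in sites:
        alternatives = _AA20.replace(out[site], "") if out[site] in _AA20 else _AA20
        out[site] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def random_protein(rng: np.random.Generator, length: int) -> str:
    """A uniform-random protein sequence starting with Met."""
    return "M" + "".join(
        _AA20[i] for i in rng.integers(len(_AA20), size=length - 1)
    )


def forge_adh_family(
    anchor: SequenceRecord,
    n: int,
    divergence: float,
    residue_overrides: dict[int, str] | None = None,
    seed: int = 0,
    indel_rate: float = 0.0,
) -> AdhFamilyResult:
    """Forge ``n`` homologs of ``anchor`` with planted active-site residues.

    Each member is mutated to ``divergence``; optional indels
    (``indel_rate`` events per 1,000 residues, geometric lengths of mean 3)
    are applied away from the override positions; finally every override
    position (1-based on the anchor) is forced to the requested residue at
    its anchor-mapped site. The truth records the planted residue per
    anchor position, giving exact ground truth for residue-mapping and
    metal-specificity recovery even across indels.
    """
    overrides = residue_overrides or {}
    for pos in overrides:
        if not 1 <= pos <= len(anchor.seq):
            raise ValueError(
                f"override position {pos} beyond anchor length {len(anchor.seq)}"
            )
    rng = np.random.default_rng(seed)
    records, planted, realized = [], {}, {}
    for i in range(n):
        mutated = mutate_protein(anchor.seq, divergence, rng)
        # carry anchor coordinates through indels: (anchor_pos | None, aa)
        cells: list[list] = [[p + 1, aa] for p, aa in enumerate(mutated)]
        if indel_rate > 0:
            n_ev = int(rng.poisson(indel_rate * len(mutated) / 1000.0))
            protected = set(overrides)
            for _ in range(n_ev):
                length = int(rng.geometric(1.0 / 3.0))
                at = int(rng.integers(0, len(cells)))
                if rng.random() < 0.5:
                    ins = [
                        [None, _AA20[k]]
                        for k in rng.integers(len(_AA20), size=length)
                    ]
                    cells[at:at] = ins
                else:
                    span = [
                        c for c in cells[at : at + length]
                        if c[0] in protected
                    ]
                    if span:  # keep planted positions alive
                        continue
                    del cells[at : at + length]
        pos_index = {c[0]: c for c in cells if c[0] is not None}
        for pos, aa in overrides.items():
            pos_index[pos][1] = aa
        seq = "".join(c[1] for c in cells)
        rid = f"{anchor.id}_m{i + 1}"
        records.append(SequenceRecord(id=rid, seq=seq, alphabet="aa"))
        planted[rid] = {pos: aa for pos, aa in overrides.items()}
        diffs = sum(a != b for a, b in zip(seq, anchor.seq))
        realized[rid] = diffs / len(anchor.seq)
    return AdhFamilyResult(
        records=tuple(records), planted_residues=planted, realized_divergence=realized
    )


@dataclass(frozen=True)
class PanScenario:
    """Forged proteome set with planted core/unique family structure."""

    proteomes: dict[str, list[SequenceRecord]]
    #: protein id -> planted family label
    family_of: dict[str, str]
    n_core: int
    n_unique_per_genome: int


def forge_proteome_set(
    n_genomes: int = 3,
    n_core: int = 20,
    n_unique: int = 5,
    divergence: float = 0.05,
    length_range: tuple[int, int] = (150, 300),
    seed: int = 0,
) -> PanScenario:
    """Proteomes with ``n_core`` shared families and ``n_unique`` singletons.

    Core members within a family diverge by ``divergence`` from a common
    base; unique proteins are fresh random sequences, so planted families
    are cleanly separated at the 50% identity cutoff.
    """
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    genome_ids = [f"G{i + 1}" for i in range(n_genomes)]
    bases = [
        random_protein(rng, int(rng.integers(lo, hi + 1))) for _ in range(n_core)
    ]
    proteomes: dict[str, list[SequenceRecord]] = {g: [] for g in genome_ids}
    family_of: dict[str, str] = {}
    for g in genome_ids:
        for j, base in enumerate(bases):
            pid = f"{g}_core{j + 1}"
            proteomes[g].append(
                SequenceRecord(
                    id=pid, seq=mutate_protein(base, divergence, rng), alphabet="aa"
                )
            )
            family_of[pid] = f"core{j + 1}"
        for j in range(n_unique):
            pid = f"{g}_uniq{j + 1}"
            proteomes[g].append(
                SequenceRecord(
                    id=pid,
                    seq=random_protein(rng, int(rng.integers(lo, hi + 1))),
                    alphabet="aa",
                )
            )
            family_of[pid] = pid
    return PanScenario(
        proteomes=proteomes,
        family_of=family_of,
        n_core=n_core,
        n_unique_per_genome=n_unique,
    )


@dataclass(frozen=True)
class CladeScenario:
    """Forged proteomes with congruent gene-content and sequence clades."""

    proteomes: dict[str, list[SequenceRecord]]
    clade_of: dict[str, str]
    planted_newick: str


def forge_clade_scenario(
    n_clades: int = 3,
    genomes_per_clade: int = 3,
    n_shared_core: int = 12,
    n_clade_specific: int = 8,
    within_divergence: float = 0.02,
    between_divergence: float = 0.2,
    length_range: tuple[int, int] = (150, 250),
    seed: int = 0,
) -> CladeScenario:
    """Clade-structured proteomes for tree-recovery tests.

    Shared core families diverge hierarchically (clade ancestors at
    ``between_divergence`` from a common base, genomes at
    ``within_divergence`` from their clade ancestor), and each clade also
    carries clade-specific families, so the binary gene-content tree and
    the core-sequence tree are congruent by construction.
    """
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    proteomes: dict[str, list[SequenceRecord]] = {}
    clade_of: dict[str, str] = {}
    clade_ids = [chr(ord("A") + c) for c in range(n_clades)]
    genome_ids = {
        c: [f"{c}{i + 1}" for i in range(genomes_per_clade)] for c in clade_ids
    }
    for c in clade_ids:
        for g in genome_ids[c]:
            proteomes[g] = []
            clade_of[g] = c

    for j in range(n_shared_core):
        base = random_protein(rng, int(rng.integers(lo, hi + 1)))
        for c in clade_ids:
            ancestor = mutate_protein(base, between_divergence, rng)
            for g in genome_ids[c]:
                proteomes[g].append(
                    SequenceRecord(
                        id=f"{g}_core{j + 1}",
                        seq=mutate_protein(ancestor, within_divergence, rng),
                        alphabet="aa",
                    )
                )
    for c in clade_ids:
        for j in range(n_clade_specific):
            base = random_protein(rng, int(rng.integers(lo, hi + 1)))
            for g in genome_ids[c]:
                proteomes[g].append(
                    SequenceRecord(
                        id=f"{g}_{c.lower()}spec{j + 1}",
                        seq=mutate_protein(base, within_divergence, rng),
                        alphabet="aa",
                    )
                )
    newick = (
        "("
        + ",".join(
            "(" + ",".join(genome_ids[c]) + ")" for c in clade_ids
        )
        + ");"
    )
    return CladeScenario(
        proteomes=proteomes, clade_of=clade_of, planted_newick=newick
    )
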