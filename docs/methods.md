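# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generators emulate, and the
numerical and design choices made where the design was genuinely open.

## Whole-genome similarity

**dDDH, formula d4.** The digital DNA–DNA hybridization statistic is the
pooled identity fraction of all high-scoring segment pairs (HSPs) between
two genomes: `100 · Σ identities / Σ aligned length`. The formula itself is
fixed; the HSP generator feeding it is not standardized across
implementations, so absolute d4 values are implementation-dependent. Here
HSPs come from a deterministic BLAST-like scan: exact nucleotide word seeds
(word size 11), ungapped X-drop extension (match +1, mismatch −2, X-drop
20), minimum HSP length 100, both strands searched per replicon pair,
overlapping HSPs on a diagonal merged with their statistics recomputed by
direct column comparison. The statistic is therefore validated by what it
must do — equal the brute-force ratio exactly, return 100 on
self-comparison, recover planted substitution divergence (d4 ≈ 100(1−p)),
and decrease strictly in p — not by matching any particular server's
output.

**Fragment ANI.** The classic fragment convention: the query genome is cut
into non-overlapping 1,020 bp fragments (terminal short fragment
discarded), each fragment is aligned to every replicon of the subject on
both strands, and fragments whose best alignment reaches ≥ 70 % identity
and ≥ 70 % coverage contribute their identity to the mean. Per-fragment
alignment uses edlib's semi-global ("infix") mode, which aligns the whole
fragment inside the subject; coverage is therefore 100 % by construction
except on degenerate subjects, and the 70 % coverage gate is kept for
interface fidelity and config symmetry. Identity is computed from the
alignment path (matched columns over all columns). The fragment method is
asymmetric in its arguments by construction; on intact synthetic pairs
ANI(a,b) and ANI(b,a) agree to well under a percentage point. Unrelated
genomes leave no fragment above the gates; that state is reported as an
explicit "no ANI signal" error, never as 0.

**GC difference.** GC% is computed over all replicons with ambiguity codes
excluded from numerator and denominator; the statistic is the absolute
difference in percentage points.

## Species delimitation

Conspecificity is the conjunction ANI ≥ 95 and dDDH ≥ 70 (both cutoffs
configurable; single-criterion modes available). The ANI default of 95
takes the lower bound of the conventional 95–96 % band: conservative in
the sense that raising it only splits groups (monotone refinement, which
is property-tested). Synonym groups are connected components (union–find
semantics) of the conspecific graph; non-transitive components are merged
— components are the transitive closure — but warn. Proposed names follow
a user-supplied nomenclatural priority table when given, else the
lexicographically smallest member; priority is never inferred from
strings. The 70–79 % dDDH band sometimes read as a subspecies signal is
surfaced in the data but never acted on automatically.

## Ortholog screening and cluster conservation

Reference proteins are aligned to each proteome member by Smith–Waterman
(BLOSUM62, affine gap 11 + k, i.e. open 12 / extend 1 in the aligner's
accounting). A hit is retained when identity ≥ 50 % and e-value ≤ 0.001;
per query and genome only the best hit survives (highest identity, ties to
longer alignment, then smaller target id — fully deterministic). Identity
is identical columns over aligned columns by default; a config switch
(`identity_over="query"`) divides by aligned query residues instead, since
the convention behind a published "50 % identity" is often unstated.

**E-values.** Expectations follow Karlin–Altschul, `E = K·m·n·e^(−λS)`,
with n the total proteome (database) length. The default constants
λ = 0.217, K = 0.018 were fitted to this aligner's own null score
distribution (10,000 local alignments of uniform-random protein pairs at
200/300/500 residues; the fit reproduces empirical tail probabilities
across all three sizes). Published BLAST constants (λ = 0.267, K = 0.041)
embed edge- and composition-corrections specific to NCBI BLAST and
underestimate this aligner's tail several-fold near the E = 0.001 decision
boundary; both constants remain overridable per call.

**Conservation rule.** Cluster completeness is `100 · present / total`;
a cluster is conserved only when *more than* 75 % of its genes are present
— strictly, so 3 of 4 (75.0 %) is not conserved. An optional stricter mode
additionally requires every essential-flagged gene.

**Context check.** An anchor hit is "in its cluster" when every partner
gene has a retained hit on the same replicon with at most
`max_intervening` genes (by rank, strand-agnostic) between it and the
anchor. The window default of 5 intervening genes is a documented
stand-in: no quantitative definition of "within a cluster" is standard,
and the parameter is exposed.

## Pan-genome

Families come from greedy centroid clustering: proteins sorted by
descending length (ties by genome then protein id) join the first family
whose founding representative they match at ≥ 50 %, else found a family.
Family identity follows the CD-HIT convention — identical columns of the
best local alignment divided by the shorter sequence length. Raw
local-alignment identity (over aligned columns) was rejected for this
role: on unrelated protein pairs the best-scoring local alignment is a
short segment whose identity is routinely 35–65 %, which makes a 50 %
family cutoff meaningless; normalizing by the shorter sequence restores a
clean separation between homologs and noise. On planted scenarios the
greedy partition equals the independent all-vs-all single-linkage
partition at the same cutoff, which bounds the greedy/graph discrepancy at
zero for well-separated families.

Core = families spanning all genomes, unique = exactly one, accessory =
the rest; a family spanning all but one genome counts as "exclusively
absent" for the missing genome. Partition conservation (Σ family sizes =
Σ proteome sizes, no protein in two families) is asserted in tests.

**Trees.** The gene-content tree applies neighbor joining to Jaccard
distances between binary genome columns (Jaccard rather than simple
matching: robust to genome-size imbalance; a Hamming switch exists). The
core tree averages per-family pairwise global-alignment p-distances (gap
columns count as differences; one member per genome, first by protein id)
across core families and hands the mean matrix to NJ. Averaging pairwise
distances deliberately avoids multiple sequence alignment and
concatenation: it removes a heavyweight dependency while preserving the
property the tree is used for, clade recovery, which is tested by RF = 0
against planted 3-clade scenarios. Negative NJ branch lengths are clamped
to zero. NJ's exactness on additive matrices (4–8 leaves) is exercised as
a sanity property.

## PQQ-ADH classification

Harvest keeps proteome members reaching ≥ 50 % identity and e ≤ 0.001
against *any* labeled anchor, deduplicated by protein id. Active-site
residues are read off a global alignment to a reference in mature-SolV-XoxF
numbering at configured positions (104, 105, 131, 132, 172, 256, 269, 299,
300, 301); a candidate aligning to < 50 % of the reference is rejected as
unmappable, and positions deleted in the candidate report a gap symbol.
Metal specificity: D301 → Ln, A301 → Ca, anything else → "other" with the
residue reported (the type-2a group's conserved S301 lands here by
design). The 131–132 double cysteine is reported as a boolean catalytic
flag — its absence never vetoes harvest, since some minor groups lack it —
and W300 is flagged as the XoxF3-vs-XoxF5 indicator (XoxF5 carries
Tyr/Phe).

Group assignment takes the nearest anchor by local-alignment identity,
requires it to reach a 50 % floor (else unassigned), and cross-checks by
neighbor joining on the candidate-plus-anchors identity-distance matrix:
if the anchor nearest by tree path disagrees, the assignment is flagged
discordant rather than silently accepted.

**The shipped reference and anchors are synthetic.** The real mature SolV
XoxF sequence is not bundled; `make_reference` and `make_default_anchors`
generate deterministic stand-ins that carry the canonical residues and
per-group signatures at the configured positions (anchors at 35 %
divergence from the reference, mutually ~45 % identical — inside the
harvest gate for their own families, outside it for decoys). They exercise
the machinery and define the coordinate system; real analyses should
supply their own reference FASTA and labeled anchors, and treat absolute
numbering (the mature-peptide offset) as configuration.

## Module profiling

MCR is `100 · satisfied steps / total steps`, a step being satisfied when
any of its alternative genes is present; it is monotone under gene-set
growth. Binarization defaults to MCR = 100 (a module "occurs" only when
complete) — the threshold behind published binary module matrices is
usually unstated, so the cut is explicit and configurable. The occurrence
filter keeps modules present in at least 4 but fewer than 65 genomes
(inclusive/exclusive exactly as stated, boundaries tested) and is
idempotent. Specificity: a module is specific to a clade set S (single
clade or union of up to two) when present in ≥ `presence_floor` (default
1.0, i.e. strict) of each member clade and absent outside S; with the
strict floor, specific modules partition disjointly across disjoint
clades.

## Inhibition statistic

`100 · (cr − ir) / cr` with cr > 0; strictly decreasing in ir and
invariant under common rescaling of both radii. Negative values (growth
stimulation) are reported as-is and flagged, never clamped. Replicates
aggregate by arithmetic mean with the sample standard deviation
(technical triplicates in the intended assay).

## Synthetic data: what it emulates, and what it does not

`ppfm.synth` emulates the *shape* of real methylotroph assemblies at
reduced scale: one or a few replicons, dense single-exon CDS annotation
on both strands, high GC (defaults target 66 %, within the 65.9–72.7 %
range typical of the group), gene lengths 300–1,200 bp. Intergenic
composition is solved by exact base count so each replicon's realized GC
hits its target up to rounding. Substitutions are uniform over sites with
a 2:1 transition:transversion ratio — downstream identity statistics
depend only on the mismatch proportion, not the spectrum — and exactly
`round(p·L)` sites change per replicon, so realized divergence equals the
specification up to rounding. Coding frames are protected: substitutions
creating in-frame stops are redrawn to a different base at the same site
(preserving the mismatch count), and indels (Poisson per kb, geometric
lengths of mean 3 bp) fall only in intergenic sequence with gene
coordinates remapped through them. Proteins are always re-derived from
the mutated nucleotide sequence, keeping nucleotide- and protein-level
screens consistent.

Cluster implantation back-translates reference proteins (uniform
synonymous codons), inserts them at intergenic points — contiguously with
a configurable number of forged filler genes between consecutive members,
or scattered — and returns the implanted gene ids as truth. The first
`round(f·n)` genes in cluster order are implanted, deterministically; a
fraction yielding zero genes warns and leaves the genome unchanged. ADH
families are forged at the protein level with planted residues written at
anchor-mapped positions, surviving optional indels.

What the generators do *not* model: rearrangement, duplication and
horizontal transfer, codon usage and amino-acid composition bias,
phylogenetically correlated divergence along a tree (clade scenarios use
a single two-level hierarchy), operon structure or strand bias, and
sequencing/assembly artifacts. Passing recovery tests therefore shows the
statistics and decision rules are implemented correctly and recover
planted signal under clean conditions; it does not show robustness to the
full messiness of real assemblies — in particular, uniform-random decoy
proteins are a weaker null than real paralog-rich proteomes.

## Numerical choices and degenerate inputs

- Coordinates are 1-based inclusive everywhere (GFF3 convention);
  half-open arithmetic stays inside algorithms.
- d4 on an empty HSP list, ANI with no qualifying fragment, trees on a
  single genome, searches on empty inputs: all explicit errors, never
  silent zeros.
- All tie-breaks (hit dedup, clustering order, nearest anchors) are
  deterministic; every stochastic generator takes an explicit seed and is
  reproducible bit-for-bit.
- Test and acceptance problem sizes (100 kb genomes for divergence
  recovery, 20 kb hosts for screening, 3 genomes × 15–25 proteins for
  pan-genome oracles, 6–20-member ADH families) were chosen as the
  smallest scales at which the measured statistics are stable against
  their tolerances.

## Known limitations

- Absolute d4 values depend on the HSP generator; only the formula, its
  limits and its monotone response to divergence are portable claims.
- The e-value model is calibrated for the default scoring system on
  uniform-random sequences; changing matrix or gap costs invalidates the
  default λ, K.
- Greedy centroid clustering can split families near the identity cutoff
  where single-linkage would join them (and vice versa); the equivalence
  holds for well-separated families.
- The ADH group taxonomy is exactly as expressive as the anchor set:
  candidates from families without an anchor can only land in
  "unassigned", and the synthetic anchors are placeholders for real
  reference sequences.
- Module specificity with unions above two clades is not searched by
  default (`max_union=2`).
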