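"""Pairwise whole-genome similarity: dDDH (formula d4), fragment ANI, GC%.

The dDDH statistic follows the intergenomic-distance formula d4: 100 times
the sum of identities over all high-scoring segment pairs (HSPs) divided by
the total aligned length of those HSPs. HSPs are generated by a
deterministic BLAST-like seed-and-extend scan (exact nucleotide word seeds,
ungapped X-drop extension); absolute d4 values are therefore
implementation-dependent, and the statistic is validated by recovery of
planted divergence and by monotonicity, not by matching any particular
server's output.

ANI uses the classic fragment convention: the query genome is cut into
non-overlapping 1,020 bp fragments, each is aligned to the subject
(semi-global, both strands), and fragments aligning with >= 70% identity
and >= 70% coverage contribute their identity to the mean. The fragment
method is asymmetric by construction; ANI(a, b) and ANI(b, a) agree only to
within about a percentage point.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .io import Genome

_RC = bytes.maketrans(b"ACGT", b"TGCA")


class NoAniSignal(RuntimeError):
    """No fragment passed the ANI inclusion thresholds (unrelated genomes)."""


@dataclass(frozen=True)
class HspParams:
    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    xdrop: int = 20
    min_length: int = 100


@dataclass(frozen=True)
class AniParams:
    fragment_len: int = 1020
    min_identity: float = 70.0
    min_coverage: float = 70.0


@dataclass(frozen=True)
class HSP:
    """A high-scoring segment pair; houses the d4 numerator and denominator.

    Coordinates are 1-based inclusive and always forward on both genomes;
    ``strand`` is '-' when the match is to the reverse complement of b.
    """

    a_replicon: str
    b_replicon: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    length: int
    identities: int
    score: int
    strand: str = "+"

    def __post_init__(self):
        if not 0 <= self.identities <= self.length:
            raise ValueError("identities must be within [0, length]")


@dataclass(frozen=True)
class SimilarityResult:
    genome_a: str
    genome_b: str
    ddh_d4: float
    ani: float
    ani_fragments_used: int
    gc_diff: float


def _extend(A: np.ndarray, B: np.ndarray, i0: int, j0: int, direction: int,
            params: HspParams, chunk: int = 4096):
    """Ungapped X-drop extension along one diagonal.

    Starting at (i0, j0) and moving in ``direction`` (+1 right, -1 left),
    consume columns until the running score falls more than ``xdrop`` below
    its maximum. Returns (steps, score, identities) at the maximum-scoring
    endpoint; steps counts consumed columns (0 = nothing gained).
    """
    best_steps, best_score, best_ident = 0, 0, 0
    score, ident, step = 0, 0, 0
    while True:
        if direction > 0:
            ai, bj = i0 + step, j0 + step
            n = min(len(A) - ai, len(B) - bj, chunk)
            if n <= 0:
                break
            m = A[ai : ai + n] == B[bj : bj + n]
        else:
            ai, bj = i0 - step, j0 - step
            n = min(ai + 1, bj + 1, chunk)
            if n <= 0:
                break
            m = A[ai - n + 1 : ai + 1][::-1] == B[bj - n + 1 : bj + 1][::-1]
        cs = score + np.cumsum(np.where(m, params.match, params.mismatch))
        ci = ident + np.cumsum(m)
        rm = np.maximum(np.maximum.accumulate(cs), best_score)
        dropped = rm - cs > params.xdrop
        stop_at = int(np.argmax(dropped)) if dropped.any() else n
        if stop_at > 0:
            k = int(np.argmax(cs[:stop_at]))
            if cs[k] > best_score:
                best_score = int(cs[k])
                best_steps = step + k + 1
                best_ident = int(ci[k])
        if dropped.any():
            break
        score, ident = int(cs[-1]), int(ci[-1])
        step += n
    return best_steps, best_score, best_ident


def _hsps_for_arrays(A: np.ndarray, B: np.ndarray, params: HspParams):
    """Seed-and-extend HSPs of A vs B (both plain forward uint8 arrays)."""
    k = params.word_size
    if len(A) < k or len(B) < k:
        return []
    index: dict[bytes, list[int]] = {}
    bview = B.tobytes()
    for j in range(len(B) - k + 1):
        index.setdefault(bview[j : j + k], []).append(j)
    aview = A.tobytes()
    covered: dict[int, int] = {}  # diagonal -> a index covered through
    raw = []
    for i in range(len(A) - k + 1):
        hits = index.get(aview[i : i + k])
        if not hits:
            continue
        for j in hits:
            d = i - j
            if i <= covered.get(d, -1):
                continue
            r_steps, r_score, r_ident = _extend(A, B, i + k, j + k, +1, params)
            l_steps, l_score, l_ident = _extend(A, B, i - 1, j - 1, -1, params)
            a_start = i - l_steps
            a_end = i + k - 1 + r_steps
            length = a_end - a_start + 1
            identities = k + l_ident + r_ident
            score = k * params.match + l_score + r_score
            covered[d] = a_end
            if length >= params.min_length:
                raw.append((d, a_start, a_end, identities, score))
    return _merge_same_diagonal(A, B, raw, params)


def _merge_same_diagonal(A, B, raw, params: HspParams):
    """Merge overlapping HSPs sharing a diagonal, recomputing their stats."""
    by_diag: dict[int, list] = {}
    for rec in raw:
        by_diag.setdefault(rec[0], []).append(rec)
    out = []
    for d, recs in by_diag.items():
        recs.sort(key=lambda r: r[1])
        merged = [list(recs[0])]
        for rec in recs[1:]:
            if rec[1] <= merged[-1][2] + 1:
                lo, hi = merged[-1][1], max(merged[-1][2], rec[2])
                m = int(np.sum(A[lo : hi + 1] == B[lo - d : hi + 1 - d]))
                n = hi - lo + 1
                merged[-1] = [d, lo, hi, m, params.match * m + params.mismatch * (n - m)]
            else:
                merged.append(list(rec))
        out.extend(tuple(r) for r in merged)
    return out


def _as_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_hsps(a: Genome, b: Genome, params: HspParams | None = None) -> list[HSP]:
    """All HSPs between two genomes, both strands, per replicon pair."""
    params = params or HspParams()
    if a.size_bp == 0 or b.size_bp == 0:
        raise ValueError("cannot find HSPs against an empty genome")
    hsps: list[HSP] = []
    for a_id, a_rep in a.replicons.items():
        A = _as_array(a_rep.seq)
        for b_id, b_rep in b.replicons.items():
            for strand in "+-":
                if strand == "+":
                    B = _as_array(b_rep.seq)
                else:
                    B = _as_array(b_rep.seq.translate(_RC)[::-1])
                for d, a_s, a_e, ident, score in _hsps_for_arrays(A, B, params):
                    b_s0, b_e0 = a_s - d, a_e - d  # 0-based on oriented B
                    if strand == "-":
                        L = len(B)
                        b_s0, b_e0 = L - 1 - b_e0, L - 1 - b_s0
                    hsps.append(
                        HSP(
                            a_replicon=a_id,
                            b_replicon=b_id,
                            a_start=a_s + 1,
                            a_end=a_e + 1,
                            b_start=b_s0 + 1,
                            b_end=b_e0 + 1,
                            length=a_e - a_s + 1,
                            identities=ident,
                            score=score,
                            strand=strand,
                        )
                    )
    return hsps


def ddh_d4(hsps: Sequence[HSP]) -> float:
    """Digital DDH by formula d4: 100 x sum(identities) / sum(lengths)."""
    if not hsps:
        raise ValueError("d4 is undefined on an empty HSP list")
    total_len = sum(h.length for h in hsps)
    total_ident = sum(h.identities for h in hsps)
    return 100.0 * total_ident / total_len


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _fragment_identity(frag: str, target: str) -> tuple[float, float]:
    """Best semi-global alignment of a fragment in a target.

    Returns (identity %, coverage %) over the alignment columns. The whole
    fragment is aligned (infix mode), so coverage is 100 unless the target
    is shorter than the fragment.
    """
    res = edlib.align(frag, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return 0.0, 0.0
    counts = {"=": 0, "X": 0, "I": 0, "D": 0, "M": 0}
    for num, op in _CIGAR_RE.findall(res["cigar"]):
        counts[op] += int(num)
    columns = sum(counts.values())
    matches = counts["="] + max(0, counts["M"] - res["editDistance"])
    query_consumed = counts["="] + counts["X"] + counts["I"] + counts["M"]
    identity = 100.0 * matches / columns if columns else 0.0
    coverage = 100.0 * query_consumed / len(frag)
    return identity, coverage


def ani_fragment(
    a: Genome, b: Genome, params: AniParams | None = None
) -> tuple[float, int]:
    """Fragment-based average nucleotide identity of a against b.

    Each full-length 1,020 bp fragment of a is aligned to every replicon of
    b on both strands; the best alignment per fragment contributes its
    identity when it clears the 70% identity / 70% coverage gates. The
    terminal short fragment of each replicon is discarded. Raises
    :class:`NoAniSignal` when no fragment qualifies.
    """
    params = params or AniParams()
    targets: list[str] = []
    for rep in b.replicons.values():
        targets.append(rep.seq)
        targets.append(rep.seq.translate(_RC)[::-1])
    if not targets:
        raise ValueError("subject genome is empty")
    identities = []
    n_fragments = 0
    for rep in a.replicons.values():
        seq = rep.seq
        for start in range(0, len(seq) - params.fragment_len + 1, params.fragment_len):
            frag = seq[start : start + params.fragment_len]
            n_fragments += 1
            best_id, best_cov = 0.0, 0.0
            for target in targets:
                ident, cov = _fragment_identity(frag, target)
                if ident > best_id:
                    best_id, best_cov = ident, cov
            if best_id >= params.min_identity and best_cov >= params.min_coverage:
                identities.append(best_id)
    if n_fragments == 0:
        raise ValueError("query genome shorter than one fragment")
    if not identities:
        raise NoAniSignal(
            f"no ANI signal: 0 of {n_fragments} fragments passed "
            f"{params.min_identity}% identity / {params.min_coverage}% coverage"
        )
    return float(np.mean(identities)), len(identities)


def gc_content(genome: Genome) -> float:
    """GC% over all replicons; ambiguity codes excluded from both counts."""
    gc = acgt = 0
    for rep in genome.replicons.values():
        for base, n in zip(*np.unique(list(rep.seq), return_counts=True)):
            if base in "GC":
                gc += int(n)
            if base in "ACGT":
                acgt += int(n)
    if acgt == 0:
        raise ValueError("genome has no unambiguous bases")
    return 100.0 * gc / acgt


def gc_diff(a: Genome, b: Genome) -> float:
    """Absolute GC% difference between two genomes, in percentage points."""
    return abs(gc_content(a) - gc_content(b))


def compare_genomes(
    a: Genome,
    b: Genome,
    hsp_params: HspParams | None = None,
    ani_params: AniParams | None = None,
) -> SimilarityResult:
    """Full pairwise comparison: d4 dDDH, fragment ANI and GC difference."""
    hsps = find_hsps(a, b, hsp_params)
    ani, used = ani_fragment(a, b, ani_params)
    return SimilarityResult(
        genome_a=a.genome_id,
        genome_b=b.genome_id,
        ddh_d4=ddh_d4(hsps),
        ani=ani,
        ani_fragments_used=used,
        gc_diff=gc_diff(a, b),
    )


def write_similarity_tsv(results: Iterable[SimilarityResult], path) -> None:
    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)


def read_similarity_tsv(path) -> list[SimilarityResult]:
    df = pd.read_csv(path, sep="\t")
    return [SimilarityResult(**row) for row in df.to_dict("records")]
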