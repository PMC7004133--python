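"""Shared sequence primitives.

Affine-gap global alignment, seed-and-extend local mapping of short queries
against a genome, identity/coverage metrics and the Kimura two-parameter
(K2P) substitution distance.  All coordinates are 0-based half-open.

The K2P distance separates the transition proportion ``P`` (A<->G, C<->T)
from the transversion proportion ``Q`` and corrects multiple hits with

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

which is the workhorse statistic for dating LTR-retrotransposon insertions
from the divergence of their two terminal repeats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

DNA = "ACGTN"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class AlignmentInputError(ValueError):
    """Raised on empty sequences or letters outside {A,C,G,T,N}."""


class SaturationError(ValueError):
    """K2P distance undefined: 1-2P-Q <= 0 or 1-2Q <= 0."""


def revcomp(seq: str) -> str:
    """Reverse complement (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignParams:
    """Needle/BLASTn-like scoring.

    Gap of length L costs ``gap_open + gap_extend * L`` (penalties are
    positive numbers here).
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 5.0
    gap_extend: float = 2.0


@dataclass(frozen=True)
class MapParams:
    """Seed-and-extend mapping thresholds.

    A deterministic, database-free stand-in for an E-value cutoff: hits are
    kept when ``score >= min_score`` and ``identity >= min_identity``.
    Seed clusters below ``min_cluster_seeds`` exact k-mer matches are not
    extended (a single random 13-mer match cannot reach the score floor).
    """

    k: int = 13
    min_score: float = 50.0
    min_identity: float = 0.75
    band: int = 30
    window_pad: int = 60
    max_kmer_occurrences: int = 50
    min_cluster_seeds: int = 3
    align: AlignParams = field(default_factory=AlignParams)


@dataclass
class PairwiseAlignment:
    query_id: str
    target_id: str
    aligned_query: str
    aligned_target: str
    score: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_target):
            raise ValueError("gapped rows differ in length")

    def columns(self):
        return zip(self.aligned_query, self.aligned_target)

    def pretty(self, width: int = 60) -> str:
        """Pairwise text dump for debugging."""
        out = []
        for i in range(0, len(self.aligned_query), width):
            a = self.aligned_query[i : i + width]
            b = self.aligned_target[i : i + width]
            m = "".join("|" if x == y and x != "-" else " " for x, y in zip(a, b))
            out.append(f"{a}\n{m}\n{b}\n")
        return "\n".join(out)


@dataclass(frozen=True)
class K2PResult:
    P: float
    Q: float
    K: float
    compared_sites: int


@dataclass(frozen=True)
class FlankHit:
    target_sequence_id: str
    target_span: tuple[int, int]
    strand: str
    identity: float
    coverage: float
    score: float


def _check_seq(seq: str, name: str) -> str:
    if not seq:
        raise AlignmentInputError(f"{name} sequence is empty")
    seq = seq.upper()
    if any(c not in DNA for c in set(seq)):
        bad = sorted(set(seq) - set(DNA))
        raise AlignmentInputError(f"{name} contains non-DNA letters {bad}")
    return seq


@lru_cache(maxsize=16)
def _aligner(params: AlignParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    mat = substitution_matrices.Array(DNA, dims=2)
    for a in DNA:
        for b in DNA:
            if a == "N" or b == "N":
                mat[a, b] = 0.0  # N is scored neutrally
            else:
                mat[a, b] = params.match if a == b else params.mismatch
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def global_align(
    a: str,
    b: str,
    params: AlignParams | None = None,
    query_id: str = "query",
    target_id: str = "target",
) -> PairwiseAlignment:
    """Optimal global (Needleman-Wunsch) alignment with affine gaps.

    Deterministic: of the co-optimal alignments the first in the aligner's
    canonical traceback order is returned.
    """
    params = params or AlignParams()
    a = _check_seq(a, "first")
    b = _check_seq(b, "second")
    aln = _aligner(params, "global").align(a, b)[0]
    return PairwiseAlignment(
        query_id=query_id,
        target_id=target_id,
        aligned_query=str(aln[0]),
        aligned_target=str(aln[1]),
        score=float(aln.score),
        query_span=(0, len(a)),
        target_span=(0, len(b)),
    )


def global_score(a: str, b: str, params: AlignParams | None = None) -> float:
    """Optimal global alignment score only (no traceback)."""
    params = params or AlignParams()
    return float(_aligner(params, "global").score(_check_seq(a, "first"), _check_seq(b, "second")))


def identity_coverage(aln: PairwiseAlignment) -> tuple[float, float]:
    """(identity, coverage) of a pairwise alignment.

    identity: matches / aligned residue-residue columns (gap and N columns
    excluded from the denominator only for gaps; N-N counts as a column but
    never as a match).  coverage: residue-residue columns / length of the
    longer of the two sequences — the conservative reading of a "fraction of
    their length" criterion when lengths differ.
    """
    matches = 0
    aligned_cols = 0
    for x, y in aln.columns():
        if x == "-" or y == "-":
            continue
        aligned_cols += 1
        if x == y and x != "N":
            matches += 1
    la = sum(1 for c in aln.aligned_query if c != "-")
    lb = sum(1 for c in aln.aligned_target if c != "-")
    denom = max(la, lb)
    identity = matches / aligned_cols if aligned_cols else 0.0
    coverage = aligned_cols / denom if denom else 0.0
    return identity, coverage


def k2p_from_counts(p_count: int, q_count: int, sites: int) -> K2PResult:
    """K2P distance from raw transition/transversion counts."""
    if sites <= 0:
        raise AlignmentInputError("no gap-free, non-N columns to compare")
    P = p_count / sites
    Q = q_count / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P saturated (P={P:.4f}, Q={Q:.4f}): distance undefined"
        )
    K = -0.5 * math.log(w1 * math.sqrt(w2))
    if p_count == 0 and q_count == 0:
        K = 0.0
    return K2PResult(P=P, Q=Q, K=K, compared_sites=sites)


def k2p_distance(aln: PairwiseAlignment) -> K2PResult:
    """K2P distance over the gap-free, non-N columns of an alignment."""
    p_count = q_count = sites = 0
    for x, y in aln.columns():
        if x in "-N" or y in "-N":
            continue
        sites += 1
        if x == y:
            continue
        if (x, y) in TRANSITIONS:
            p_count += 1
        else:
            q_count += 1
    return k2p_from_counts(p_count, q_count, sites)


# ---------------------------------------------------------------------------
# seed-and-extend mapping


_BASE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i


def kmer_ids(seq: str, k: int) -> np.ndarray:
    """Integer ids of all k-mers of ``seq`` (int64; -1 where the window
    contains a non-ACGT letter)."""
    codes = _BASE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    ids = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        bad |= window >= 4
        ids = ids * 4 + window
    ids[bad] = -1
    return ids


class GenomeIndex:
    """Exact k-mer index over a set of genome sequences.

    Build once per genome, then :meth:`map` short queries repeatedly.
    Per sequence the k-mer ids are kept sorted with their positions, so a
    query k-mer resolves by binary search without a hash table.  k-mers
    containing N and k-mers above ``max_occurrences`` are skipped (repeat
    masking in miniature).
    """

    def __init__(self, sequences: dict[str, str], k: int = 13, max_occurrences: int = 50):
        if not sequences or all(len(s) == 0 for s in sequences.values()):
            raise AlignmentInputError("genome is empty")
        self.k = k
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        self.max_occurrences = max_occurrences
        self._sorted: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, seq in self.sequences.items():
            ids = kmer_ids(seq, k)
            order = np.argsort(ids, kind="stable")
            self._sorted[name] = (ids[order], order.astype(np.int64))

    def seed_hits(self, query: str) -> dict[tuple[str, str], list[tuple[int, int]]]:
        """(target, strand) -> [(qpos, tpos), ...] exact k-mer matches."""
        out: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for strand, q in (("+", query), ("-", revcomp(query))):
            qids = kmer_ids(q, self.k)
            valid = np.flatnonzero(qids >= 0)
            if valid.size == 0:
                continue
            for name, (sids, spos) in self._sorted.items():
                lo = np.searchsorted(sids, qids[valid], side="left")
                hi = np.searchsorted(sids, qids[valid], side="right")
                counts = hi - lo
                take = np.flatnonzero((counts > 0) & (counts <= self.max_occurrences))
                if take.size == 0:
                    continue
                seeds = out.setdefault((name, strand), [])
                for t in take:
                    qpos = int(valid[t])
                    for tpos in spos[lo[t] : hi[t]]:
                        seeds.append((qpos, int(tpos)))
        return out

    def map(self, query: str, params: MapParams | None = None) -> list[FlankHit]:
        """Map a query against the genome; hits sorted by score descending.

        Seeds are clustered by diagonal, each cluster is re-aligned locally
        inside a padded window and the resulting hit is reported with
        identity (matches over aligned columns) and coverage (aligned query
        residues over query length).
        """
        params = params or MapParams()
        query = _check_seq(query, "query")
        if len(query) < params.k:
            raise AlignmentInputError(
                f"query shorter than seed length ({len(query)} < {params.k})"
            )
        aligner = _aligner(params.align, "local")
        hits: list[FlankHit] = []
        for (name, strand), seeds in self.seed_hits(query).items():
            target = self.sequences[name]
            q = query if strand == "+" else revcomp(query)
            for cluster in _cluster_seeds(seeds, params.band, len(q)):
                if len(cluster) < params.min_cluster_seeds:
                    continue
                lo = min(t - i for i, t in cluster)
                hi = max(t - i for i, t in cluster)
                w0 = max(0, lo - params.window_pad)
                w1 = min(len(target), hi + len(q) + params.window_pad)
                window = target[w0:w1]
                try:
                    aln = aligner.align(q, window)[0]
                except IndexError:
                    continue
                pa = PairwiseAlignment(
                    query_id="query",
                    target_id=name,
                    aligned_query=str(aln[0]),
                    aligned_target=str(aln[1]),
                    score=float(aln.score),
                    query_span=(int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])),
                    target_span=(int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1])),
                )
                matches = sum(
                    1 for x, y in pa.columns() if x == y and x not in "-N"
                )
                cols = sum(1 for x, y in pa.columns() if x != "-" and y != "-")
                identity = matches / cols if cols else 0.0
                coverage = cols / len(query)
                t0 = w0 + pa.target_span[0]
                t1 = w0 + pa.target_span[1]
                if pa.score < params.min_score or identity < params.min_identity:
                    continue
                hits.append(
                    FlankHit(
                        target_sequence_id=name,
                        target_span=(t0, t1),
                        strand=strand,
                        identity=identity,
                        coverage=coverage,
                        score=pa.score,
                    )
                )
        hits.sort(key=lambda h: (-h.score, h.target_sequence_id, h.target_span))
        return _dedupe_hits(hits)


def _cluster_seeds(
    seeds: list[tuple[int, int]], band: int, qlen: int
) -> list[list[tuple[int, int]]]:
    """Group seeds into diagonal bands, then split distant groups on the target."""
    by_diag = sorted(seeds, key=lambda s: (s[1] - s[0], s[1]))
    clusters: list[list[tuple[int, int]]] = []
    cur: list[tuple[int, int]] = []
    last_diag = None
    for qpos, tpos in by_diag:
        d = tpos - qpos
        if last_diag is None or abs(d - last_diag) <= band:
            cur.append((qpos, tpos))
        else:
            clusters.append(cur)
            cur = [(qpos, tpos)]
        last_diag = d
    if cur:
        clusters.append(cur)
    # split clusters whose members are far apart on the target
    out = []
    for cluster in clusters:
        cluster.sort(key=lambda s: s[1])
        run = [cluster[0]]
        for seed in cluster[1:]:
            if seed[1] - run[-1][1] > 2 * qlen:
                out.append(run)
                run = [seed]
            else:
                run.append(seed)
        out.append(run)
    return out


def _dedupe_hits(hits: list[FlankHit]) -> list[FlankHit]:
    """Keep the best-scoring hit per overlapping target locus."""
    kept: list[FlankHit] = []
    for h in hits:
        redundant = False
        for k in kept:
            if (
                k.target_sequence_id == h.target_sequence_id
                and k.strand == h.strand
                and _overlap_len(k.target_span, h.target_span) > 0.5 * _span_len(h.target_span)
            ):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def _span_len(span: tuple[int, int]) -> int:
    return max(0, span[1] - span[0])


def _overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def map_flank(query: str, genome: dict[str, str], params: MapParams | None = None) -> list[FlankHit]:
    """One-shot convenience over :class:`GenomeIndex` (re-indexes the genome)."""
    params = params or MapParams()
    return GenomeIndex(genome, k=params.k, max_occurrences=params.max_kmer_occurrences).map(
        query, params
    )
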