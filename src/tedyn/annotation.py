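"""Structural annotation of LTR retrotransposons and MITE copies.

A candidate LTR retrotransposon is a pair of similar terminal repeats at an
element-scale separation, flanking an internal region that codes for the
retroviral-like domains (GAG, PR, INT, RT, RH).  The detector here is a
simplified structural scanner: exact k-mer self-matches seed candidate
repeat pairs, which are extended by ungapped X-drop comparison and
validated against length and identity constraints.  Parity with any
particular external annotation tool is not claimed.

Downstream filters remove non-coding elements, single-copy (unreproducible)
elements, gap-rich and tandem-repeat-rich candidates; the survivors are
classified into the Copia and Gypsy superfamilies by the order of the
integrase (INT) and reverse transcriptase (RT) domains on the coding
strand: INT before RT is Copia, RT before INT is Gypsy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .align import AlignParams, GenomeIndex, MapParams, global_align, identity_coverage

DOMAINS = ("GAG", "PR", "INT", "RT", "RH")


@dataclass(frozen=True)
class DomainHit:
    domain: str
    span_on_element: tuple[int, int]
    strand: str = "+"


@dataclass
class LTRElement:
    element_id: str
    sequence_id: str
    span: tuple[int, int]
    ltr5_span: tuple[int, int]
    ltr3_span: tuple[int, int]
    internal_span: tuple[int, int]
    tsd: str | None = None
    domain_hits: list[DomainHit] = field(default_factory=list)
    superfamily: str = "unclassified"
    completeness: str = "incomplete"
    gap_fraction: float = 0.0
    tandem_fraction: float = 0.0

    def __post_init__(self) -> None:
        s, e = self.span
        if not (s <= self.ltr5_span[0] < self.ltr5_span[1] <= self.internal_span[0]
                <= self.internal_span[1] <= self.ltr3_span[0] < self.ltr3_span[1] <= e):
            raise ValueError(f"{self.element_id}: LTR/internal spans not nested in element span")

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]

    def sequence(self, genome: dict[str, str]) -> str:
        return genome[self.sequence_id][self.span[0] : self.span[1]]

    def ltr_sequences(self, genome: dict[str, str]) -> tuple[str, str]:
        seq = genome[self.sequence_id]
        return (
            seq[self.ltr5_span[0] : self.ltr5_span[1]],
            seq[self.ltr3_span[0] : self.ltr3_span[1]],
        )


@dataclass(frozen=True)
class MITECopy:
    family_id: str
    sequence_id: str
    span: tuple[int, int]
    consensus_length: int

    @property
    def copy_length(self) -> int:
        return self.span[1] - self.span[0]


@dataclass(frozen=True)
class LTRDetectParams:
    """Structural-detector constraints, LTRharvest-like in spirit."""

    k: int = 13
    min_ltr: int = 100
    max_ltr: int = 3000
    min_element: int = 1000
    max_element: int = 15000
    min_ltr_identity: float = 0.85
    min_seeds: int = 4
    xdrop: float = 12.0
    tsd_min: int = 4
    tsd_max: int = 6
    max_kmer_occurrences: int = 40


# ---------------------------------------------------------------------------
# detection


def detect_ltr_candidates(
    genome: dict[str, str], params: LTRDetectParams | None = None
) -> list[LTRElement]:
    """Scan a genome for candidate LTR retrotransposons.

    Substitution-divergent repeat pairs keep their exact separation, so
    seeds are grouped by exact distance; each seed run is extended by
    ungapped X-drop comparison of the two repeat copies and validated
    against the length/identity constraints.
    """
    params = params or LTRDetectParams()
    out: list[LTRElement] = []
    counter = 0
    for name in sorted(genome):
        seq = genome[name].upper()
        for cand in _detect_in_sequence(seq, params):
            counter += 1
            a5, b5, a3, b3, ident = cand
            tsd = _find_tsd(seq, a5, b3, params)
            out.append(
                LTRElement(
                    element_id=f"cand_{name}_{counter:05d}",
                    sequence_id=name,
                    span=(a5, b3),
                    ltr5_span=(a5, b5),
                    ltr3_span=(a3, b3),
                    internal_span=(b5, a3),
                    tsd=tsd,
                    gap_fraction=seq[a5:b3].count("N") / (b3 - a5),
                    tandem_fraction=tandem_fraction(seq[a5:b3]),
                )
            )
    return out


def _detect_in_sequence(seq: str, params: LTRDetectParams):
    from .align import kmer_ids

    ids = kmer_ids(seq, params.k)
    order = np.argsort(ids, kind="stable")
    sids = ids[order]
    first_valid = np.searchsorted(sids, 0, side="left")
    sids, positions = sids[first_valid:], order[first_valid:]
    boundaries = np.flatnonzero(np.diff(sids)) + 1
    groups = np.split(positions, boundaries)
    d_min = max(1, params.min_element - params.max_ltr)
    d_max = params.max_element - params.min_ltr
    pairs_by_d: dict[int, list[int]] = {}
    for group in groups:
        if len(group) < 2 or len(group) > params.max_kmer_occurrences:
            continue
        group = np.sort(group)
        for i, p1 in enumerate(group):
            for p2 in group[i + 1 :]:
                d = int(p2 - p1)
                if d_min <= d <= d_max:
                    pairs_by_d.setdefault(d, []).append(int(p1))
    if not pairs_by_d:
        return []

    candidates = []
    for d, starts in sorted(pairs_by_d.items()):
        starts.sort()
        run = [starts[0]]
        for p in starts[1:]:
            if p - run[-1] <= params.max_ltr:
                run.append(p)
            else:
                candidates.extend(_extend_run(seq, run, d, params))
                run = [p]
        candidates.extend(_extend_run(seq, run, d, params))

    # dedupe overlapping candidates, best identity wins
    candidates.sort(key=lambda c: -c[4])
    kept = []
    for cand in candidates:
        a5, b5, a3, b3, ident = cand
        if any(min(b3, kb3) - max(a5, ka5) > 0.5 * (b3 - a5) for ka5, _, _, kb3, _ in kept):
            continue
        kept.append(cand)
    kept.sort()
    return kept


def _extend_run(seq: str, run: list[int], d: int, params: LTRDetectParams):
    if len(run) < params.min_seeds:
        return []
    lo, hi = run[0], run[-1] + params.k
    a = _extend_left(seq, lo, d, params.xdrop)
    b = _extend_right(seq, hi, d, params.xdrop)
    ltr_len = b - a
    elem_len = b + d - a
    if not (params.min_ltr <= ltr_len <= params.max_ltr):
        return []
    if not (params.min_element <= elem_len <= params.max_element):
        return []
    if ltr_len > d:  # repeat copies overlap: tandem, not LTR structure
        return []
    matches = sum(1 for i in range(a, b) if seq[i] == seq[i + d])
    ident = matches / ltr_len
    if ident < params.min_ltr_identity:
        return []
    return [(a, b, a + d, b + d, ident)]


def _extend_left(seq: str, pos: int, d: int, xdrop: float) -> int:
    best, best_pos, score = 0.0, pos, 0.0
    i = pos - 1
    while i >= 0:
        score += 1.0 if seq[i] == seq[i + d] else -2.0
        if score > best:
            best, best_pos = score, i
        if best - score > xdrop:
            break
        i -= 1
    return best_pos


def _extend_right(seq: str, pos: int, d: int, xdrop: float) -> int:
    best, best_pos, score = 0.0, pos, 0.0
    i = pos
    while i + d < len(seq):
        score += 1.0 if seq[i] == seq[i + d] else -2.0
        if score > best:
            best, best_pos = score, i + 1
        if best - score > xdrop:
            break
        i += 1
    return best_pos


def _find_tsd(seq: str, start: int, end: int, params: LTRDetectParams) -> str | None:
    for length in range(params.tsd_max, params.tsd_min - 1, -1):
        if start - length < 0 or end + length > len(seq):
            continue
        left = seq[start - length : start]
        right = seq[end : end + length]
        if left == right and "N" not in left:
            return left
    return None


# ---------------------------------------------------------------------------
# filtering and classification


def tandem_fraction(seq: str, max_period: int = 12, min_run: int = 24) -> float:
    """Fraction of positions inside period-p tandem runs (p <= max_period).

    A position is tandem when it matches the base ``p`` positions earlier
    and belongs to such a run of at least ``min_run`` bp.
    """
    n = len(seq)
    if n == 0:
        return 0.0
    tandem = [False] * n
    for p in range(1, max_period + 1):
        run_start = None
        for i in range(p, n + 1):
            if i < n and seq[i] == seq[i - p] and seq[i] != "N":
                if run_start is None:
                    run_start = i - p
            else:
                if run_start is not None and i - run_start >= min_run:
                    for j in range(run_start, i):
                        tandem[j] = True
                run_start = None
    return sum(tandem) / n


def gap_fraction(seq: str) -> float:
    """Fraction of assembly-gap (N) characters."""
    return seq.count("N") / len(seq) if seq else 0.0


def count_genomic_hits(
    element_seq: str,
    index: GenomeIndex,
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
) -> int:
    """Number of 80/80-style genomic matches of a full element sequence
    (the element's own locus counts as one)."""
    params = MapParams(
        k=index.k, min_score=50.0, min_identity=min_identity,
        align=AlignParams(), max_kmer_occurrences=index.max_occurrences,
    )
    hits = index.map(element_seq, params)
    return sum(1 for h in hits if h.coverage >= min_coverage and h.identity >= min_identity)


def filter_elements(
    elements: list[LTRElement],
    genome: dict[str, str],
    domain_table: dict[str, list[DomainHit]],
    max_gap_fraction: float = 0.10,
    max_tandem_fraction: float = 0.50,
    genome_index: GenomeIndex | None = None,
    check_single_hit: bool = True,
) -> tuple[list[LTRElement], list[tuple[LTRElement, str]]]:
    """Apply the coding / single-hit / gap / tandem-repeat filters.

    Keeps coding elements (>= 1 domain hit) whose full sequence has more
    than one genomic 80/80 match, <= 10% N and <= 50% tandem-repeat
    content.  Returns (kept, [(rejected, reason), ...]).
    """
    known = {el.element_id for el in elements}
    unknown = set(domain_table) - known
    if unknown:
        raise ValueError(f"domain table references unknown elements: {sorted(unknown)[:5]}")
    if check_single_hit and genome_index is None:
        genome_index = GenomeIndex(genome, k=13)
    kept: list[LTRElement] = []
    rejected: list[tuple[LTRElement, str]] = []
    for el in elements:
        seq = el.sequence(genome)
        gf = gap_fraction(seq)
        tf = tandem_fraction(seq)
        el.gap_fraction = gf
        el.tandem_fraction = tf
        el.domain_hits = domain_table.get(el.element_id, [])
        if not el.domain_hits:
            rejected.append((el, "non_coding"))
        elif gf > max_gap_fraction:
            rejected.append((el, "gap_fraction"))
        elif tf > max_tandem_fraction:
            rejected.append((el, "tandem_fraction"))
        elif check_single_hit and count_genomic_hits(seq, genome_index) <= 1:
            rejected.append((el, "single_hit"))
        else:
            kept.append(el)
    return kept, rejected


def classify_superfamily(
    element: LTRElement, domain_hits: list[DomainHit] | None = None
) -> LTRElement:
    """Set superfamily and completeness from the internal domain order.

    The element's coding strand is the majority strand of its domain hits;
    hits on '-' are mirrored before ordering so classification is
    strand-invariant.  INT before RT (5'->3') is Copia, RT before INT is
    Gypsy; with either domain missing the element stays unclassified.
    Complete means all five of GAG, PR, INT, RT, RH are present.
    """
    hits = domain_hits if domain_hits is not None else element.domain_hits
    element.domain_hits = hits
    present = {h.domain for h in hits}
    element.completeness = "complete" if present >= set(DOMAINS) else "incomplete"
    strand_votes = Counter(h.strand for h in hits)
    strand = "+" if strand_votes.get("+", 0) >= strand_votes.get("-", 0) else "-"
    ordered = sorted(hits, key=lambda h: h.span_on_element[0], reverse=(strand == "-"))
    order = [h.domain for h in ordered]
    if "INT" in order and "RT" in order:
        element.superfamily = "Copia" if order.index("INT") < order.index("RT") else "Gypsy"
    else:
        element.superfamily = "unclassified"
    return element


def mite_full_length_filter(
    copies: list[MITECopy], tolerance: float = 0.20
) -> list[MITECopy]:
    """Keep MITE copies within consensus length +/- 20% (closed interval)."""
    out = []
    for c in copies:
        if c.consensus_length <= 0:
            raise ValueError(f"{c.family_id}: consensus_length must be positive")
        lo = (1.0 - tolerance) * c.consensus_length
        hi = (1.0 + tolerance) * c.consensus_length
        if lo <= c.copy_length <= hi:
            out.append(c)
    return out


def ltr_identity(element: LTRElement, genome: dict[str, str]) -> float:
    """Global-alignment identity of the element's two LTRs."""
    ltr5, ltr3 = element.ltr_sequences(genome)
    ident, _ = identity_coverage(global_align(ltr5, ltr3))
    return ident
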