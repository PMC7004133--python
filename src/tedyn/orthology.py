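"""Flank-anchored orthologous-insertion classification.

For each full-length LTR-retrotransposon insertion in one genome, its two
500-bp flanking sequences are mapped onto the other genome.  When both
flanks land unambiguously on the same sequence and strand, in order, with
an inner distance below 25 kb, the locus is concordant; the inter-flank
region is then aligned to the element itself and the insertion is called

* conserved — aligned over >= 80% of its length at >= 80% identity;
* specific — the inter-flank span is essentially empty (the element is
  absent in the other genome; the target-site footprint remains);
* partially_deleted_or_rearranged — a substantial inter-flank region that
  no longer matches the element.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

from .align import (
    AlignParams,
    FlankHit,
    GenomeIndex,
    MapParams,
    global_align,
    identity_coverage,
)
from .annotation import LTRElement


@dataclass(frozen=True)
class OrthoParams:
    flank_len: int = 500
    max_interflank_distance: int = 25_000
    min_identity: float = 0.80
    min_coverage: float = 0.80
    empty_site_max: int = 100
    # ambiguity filter for flank hits
    best_second_ratio: float = 1.2
    flank_min_identity: float = 0.75
    flank_min_coverage: float = 0.5
    max_flank_hits: int = 5
    overlap_slop: int = 20


@dataclass
class OrthologyCall:
    element_id: str
    locus_status: str  # concordant | discordant | unmapped
    category: str  # conserved | specific | partially_deleted_or_rearranged | unresolved
    target_sequence_id: str | None = None
    target_interflank_span: tuple[int, int] | None = None
    internal_identity: float | None = None
    internal_coverage: float | None = None
    note: str = ""


class FlankError(ValueError):
    """Element sits at a sequence edge with no flanking sequence at all."""


def extract_flanks(
    element: LTRElement, genome: dict[str, str], flank_len: int = 500
) -> tuple[str, str, bool]:
    """Up to ``flank_len`` bases either side of the element.

    Returns (left, right, truncated); raises :class:`FlankError` when a
    flank is empty (element abuts the sequence end).
    """
    if flank_len <= 0:
        raise ValueError("flank_len must be positive")
    seq = genome[element.sequence_id]
    s, e = element.span
    left = seq[max(0, s - flank_len) : s]
    right = seq[e : e + flank_len]
    if not left or not right:
        raise FlankError(f"{element.element_id}: zero-length flank at sequence edge")
    truncated = len(left) < flank_len or len(right) < flank_len
    return left, right, truncated


def _best_unambiguous(hits: list[FlankHit], params: OrthoParams) -> FlankHit | None:
    """Best hit if it is clear of the runner-up and passes the quality floor.

    TE-dense flanks (many hits) are refused rather than forced.
    """
    if not hits or len(hits) > params.max_flank_hits:
        return None
    best = hits[0]
    if best.identity < params.flank_min_identity or best.coverage < params.flank_min_coverage:
        return None
    if len(hits) > 1 and best.score < params.best_second_ratio * hits[1].score:
        return None
    return best


def find_ortholog_locus(
    left: str,
    right: str,
    target_index: GenomeIndex,
    params: OrthoParams | None = None,
    map_params: MapParams | None = None,
) -> tuple[str, str | None, tuple[int, int] | None, str | None]:
    """Locate the orthologous locus from the two flanks.

    Returns (locus_status, target_sequence_id, inter-flank span, strand).
    Concordant requires both flanks to map unambiguously to the same
    sequence and strand, in the correct left/right order after strand
    normalisation, with an inner-edge distance < 25 kb.
    """
    params = params or OrthoParams()
    map_params = map_params or MapParams()
    if not left or not right:
        raise ValueError("flanks must be non-empty")
    left_hit = _best_unambiguous(target_index.map(left, map_params), params)
    right_hit = _best_unambiguous(target_index.map(right, map_params), params)
    if left_hit is None or right_hit is None:
        return "unmapped", None, None, None
    if (
        left_hit.target_sequence_id != right_hit.target_sequence_id
        or left_hit.strand != right_hit.strand
    ):
        return "discordant", None, None, None
    strand = left_hit.strand
    # on '+' the left flank precedes the right flank on the target; on '-'
    # the order is reversed
    first, second = (left_hit, right_hit) if strand == "+" else (right_hit, left_hit)
    inner = second.target_span[0] - first.target_span[1]
    if inner < -params.overlap_slop or inner >= params.max_interflank_distance:
        return "discordant", None, None, None
    span = (first.target_span[1], max(first.target_span[1], second.target_span[0]))
    return "concordant", left_hit.target_sequence_id, span, strand


def classify_insertion(
    element: LTRElement,
    genome: dict[str, str],
    target_genome: dict[str, str],
    target_index: GenomeIndex,
    params: OrthoParams | None = None,
    map_params: MapParams | None = None,
) -> OrthologyCall:
    """Full per-element classification against the other genome."""
    params = params or OrthoParams()
    try:
        left, right, truncated = extract_flanks(element, genome, params.flank_len)
    except FlankError as exc:
        return OrthologyCall(element.element_id, "unmapped", "unresolved", note=str(exc))
    status, target_id, span, strand = find_ortholog_locus(
        left, right, target_index, params, map_params
    )
    if status != "concordant":
        return OrthologyCall(element.element_id, status, "unresolved")
    if span[1] - span[0] <= params.empty_site_max:
        return OrthologyCall(
            element.element_id, "concordant", "specific",
            target_sequence_id=target_id, target_interflank_span=span,
        )
    target_seq = target_genome[target_id][span[0] : span[1]]
    from .align import revcomp

    if strand == "-":
        target_seq = revcomp(target_seq)
    aln = global_align(element.sequence(genome), target_seq)
    identity, coverage = identity_coverage(aln)
    if identity >= params.min_identity and coverage >= params.min_coverage:
        category = "conserved"
    else:
        category = "partially_deleted_or_rearranged"
    return OrthologyCall(
        element.element_id, "concordant", category,
        target_sequence_id=target_id, target_interflank_span=span,
        internal_identity=identity, internal_coverage=coverage,
    )


def classify_all(
    elements: list[LTRElement],
    genome: dict[str, str],
    target_genome: dict[str, str],
    params: OrthoParams | None = None,
    map_params: MapParams | None = None,
    target_index: GenomeIndex | None = None,
) -> list[OrthologyCall]:
    """Classify every element of one genome against the other (index built once)."""
    map_params = map_params or MapParams()
    if target_index is None:
        target_index = GenomeIndex(
            target_genome, k=map_params.k, max_occurrences=map_params.max_kmer_occurrences
        )
    return [
        classify_insertion(el, genome, target_genome, target_index, params, map_params)
        for el in elements
    ]


def age_by_category(
    calls: list[OrthologyCall],
    ages_mya: dict[str, float],
    speciation_mya: float = 5.88,
) -> dict:
    """Per-category counts and age splits around the speciation time.

    The expectation on real genome pairs: specific insertions are mostly
    younger than the split, conserved insertions mostly older.
    """
    report: dict = {"speciation_mya": speciation_mya, "categories": {}}
    by_cat: dict[str, list[float]] = {}
    counts: dict[str, int] = {}
    for call in calls:
        counts[call.category] = counts.get(call.category, 0) + 1
        age = ages_mya.get(call.element_id)
        if age is not None:
            by_cat.setdefault(call.category, []).append(age)
    for cat, n in sorted(counts.items()):
        ages = by_cat.get(cat, [])
        entry: dict = {"count": n, "n_dated": len(ages)}
        if ages:
            entry["median_age_mya"] = median(ages)
            entry["fraction_younger_than_split"] = sum(
                1 for a in ages if a < speciation_mya
            ) / len(ages)
            entry["fraction_older_than_split"] = sum(
                1 for a in ages if a >= speciation_mya
            ) / len(ages)
        report["categories"][cat] = entry
    return report


def calls_to_rows(calls: list[OrthologyCall]) -> list[dict]:
    return [
        {
            "element_id": c.element_id,
            "locus_status": c.locus_status,
            "category": c.category,
            "target_sequence_id": c.target_sequence_id or "",
            "target_start": c.target_interflank_span[0] if c.target_interflank_span else "",
            "target_end": c.target_interflank_span[1] if c.target_interflank_span else "",
            "internal_identity": c.internal_identity if c.internal_identity is not None else "",
            "internal_coverage": c.internal_coverage if c.internal_coverage is not None else "",
        }
        for c in calls
    ]
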