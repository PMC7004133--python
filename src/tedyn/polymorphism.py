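"""Fixed/polymorphic insertion calling from cohort deletion calls.

A reference TE insertion is polymorphic when at least one resequenced
cultivar carries a filtered deletion call that overlaps it under the
one-way 80% rule (at least 80% of either the deletion or the TE covered by
the other); otherwise it is fixed.  Presence is inferred only from the
absence of a deletion call — read-level evidence is out of scope — and the
deletion calls themselves are consumed, not generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

SIZE_CLASSES = [(1, 50), (51, 500), (501, 10_000), (10_001, 50_000)]


@dataclass(frozen=True)
class DeletionCall:
    cultivar_id: str
    sequence_id: str
    span: tuple[int, int]
    support_reads: int

    def __post_init__(self) -> None:
        if self.span[1] - self.span[0] < 1:
            raise ValueError(f"deletion span {self.span} has length < 1")
        if self.support_reads < 0:
            raise ValueError("support_reads must be >= 0")

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


@dataclass
class PolymorphismStatus:
    element_id: str
    status: str  # fixed | polymorphic
    absent_in: list[str] = field(default_factory=list)
    evidence: list[DeletionCall] = field(default_factory=list)


def filter_deletions(
    calls: list[DeletionCall],
    n_regions: dict[str, list[tuple[int, int]]] | None = None,
    min_support: int = 20,
    pad: int = 1000,
) -> list[DeletionCall]:
    """Support and N-region filters.

    Keeps calls with >= ``min_support`` supporting reads in that cultivar
    that do not touch any assembly-gap (N) region expanded by ``pad`` bp on
    each side.
    """
    trees: dict[str, IntervalTree] = {}
    for seq_id, regions in (n_regions or {}).items():
        tree = IntervalTree()
        for s, e in regions:
            tree.addi(max(0, s - pad), e + pad)
        trees[seq_id] = tree
    out = []
    for call in calls:
        if call.support_reads < min_support:
            continue
        tree = trees.get(call.sequence_id)
        if tree is not None and tree.overlap(*call.span):
            continue
        out.append(call)
    return out


def deletion_te_overlap(deletion_span: tuple[int, int], te_span: tuple[int, int]) -> bool:
    """One-way 80% overlap rule (symmetric in its two intervals).

    True iff the overlap covers at least 80% of the deletion OR at least
    80% of the TE.
    """
    ov = min(deletion_span[1], te_span[1]) - max(deletion_span[0], te_span[0])
    if ov <= 0:
        return False
    len_del = deletion_span[1] - deletion_span[0]
    len_te = te_span[1] - te_span[0]
    return ov >= 0.8 * len_del or ov >= 0.8 * len_te


def classify_fixed_polymorphic(
    insertions: list[tuple[str, str, tuple[int, int]]],
    filtered_calls: list[DeletionCall],
    cohort: list[str],
) -> list[PolymorphismStatus]:
    """Per-insertion fixed/polymorphic verdicts over a cultivar cohort.

    ``insertions``: (element_id, sequence_id, span) of reference TE
    insertions.  An element is polymorphic iff at least one cohort cultivar
    has a filtered deletion overlapping it under the one-way 80% rule.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    cohort_set = set(cohort)
    by_seq: dict[str, list[DeletionCall]] = {}
    for call in filtered_calls:
        if call.cultivar_id not in cohort_set:
            continue
        by_seq.setdefault(call.sequence_id, []).append(call)
    trees = {
        seq_id: IntervalTree.from_tuples((c.span[0], c.span[1], i) for i, c in enumerate(calls))
        for seq_id, calls in by_seq.items()
    }
    out = []
    for element_id, seq_id, span in insertions:
        evidence = []
        absent: set[str] = set()
        tree = trees.get(seq_id)
        if tree is not None:
            for iv in sorted(tree.overlap(*span)):
                call = by_seq[seq_id][iv.data]
                if deletion_te_overlap(call.span, span):
                    evidence.append(call)
                    absent.add(call.cultivar_id)
        status = "polymorphic" if absent else "fixed"
        out.append(
            PolymorphismStatus(
                element_id=element_id,
                status=status,
                absent_in=sorted(absent),
                evidence=evidence,
            )
        )
    return out


def unique_events(calls: list[DeletionCall], merge_slop: int = 0) -> list[tuple[str, tuple[int, int], list[DeletionCall]]]:
    """Collapse per-cultivar calls into unique events.

    By default an event is an exact (sequence_id, start, end) triple; with
    ``merge_slop`` > 0, calls whose endpoints both lie within the slop of
    an existing event are merged into it (first-seen span kept).
    """
    events: list[tuple[str, tuple[int, int], list[DeletionCall]]] = []
    for call in sorted(calls, key=lambda c: (c.sequence_id, c.span)):
        merged = False
        for seq_id, span, members in events:
            if (
                seq_id == call.sequence_id
                and abs(span[0] - call.span[0]) <= merge_slop
                and abs(span[1] - call.span[1]) <= merge_slop
            ):
                members.append(call)
                merged = True
                break
        if not merged:
            events.append((call.sequence_id, call.span, [call]))
    return events


def size_class_summary(
    filtered_calls: list[DeletionCall],
    te_annotation: dict[str, list[tuple[int, int]]],
    merge_slop: int = 0,
) -> dict:
    """Deletion size-class table with TE-overlap percentages.

    Unique events are binned into the {1-50, 51-500, 501-10000,
    10001-50000} bp classes (larger events are reported separately); an
    event counts as TE-overlapping under the one-way 80% rule against any
    annotated TE.  Per-cultivar call counts are included.
    """
    te_trees = {
        seq_id: IntervalTree.from_tuples((s, e) for s, e in spans if e > s)
        for seq_id, spans in te_annotation.items()
    }
    events = unique_events(filtered_calls, merge_slop)
    classes = {f"{lo}-{hi}": {"events": 0, "te_overlap": 0} for lo, hi in SIZE_CLASSES}
    oversize = {"events": 0, "te_overlap": 0}
    for seq_id, span, _members in events:
        length = span[1] - span[0]
        tree = te_trees.get(seq_id)
        overlaps_te = False
        if tree is not None:
            overlaps_te = any(
                deletion_te_overlap(span, (iv.begin, iv.end)) for iv in tree.overlap(*span)
            )
        bucket = None
        for lo, hi in SIZE_CLASSES:
            if lo <= length <= hi:
                bucket = classes[f"{lo}-{hi}"]
                break
        if bucket is None:
            bucket = oversize
        bucket["events"] += 1
        if overlaps_te:
            bucket["te_overlap"] += 1
    for bucket in list(classes.values()) + [oversize]:
        bucket["te_overlap_pct"] = (
            100.0 * bucket["te_overlap"] / bucket["events"] if bucket["events"] else None
        )
    per_cultivar = (
        pd.Series([c.cultivar_id for c in filtered_calls]).value_counts().to_dict()
        if filtered_calls
        else {}
    )
    return {
        "n_unique_events": len(events),
        "size_classes": classes,
        "oversize": oversize,
        "per_cultivar_call_counts": per_cultivar,
        "presence_inference": "absence_of_deletion_call_only",
    }


def status_to_frame(statuses: list[PolymorphismStatus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "element_id": s.element_id,
                "status": s.status,
                "n_absent": len(s.absent_in),
                "absent_in": ",".join(s.absent_in),
            }
            for s in statuses
        ]
    )
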