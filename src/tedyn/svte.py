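"""Between-genome structural-variant filtering and TE association.

Variant tables are Assemblytics-shaped: each record carries a type
(insertion / deletion / repeat or tandem expansion / contraction), spans on
both genomes and a size.  After the 20 bp - 25 kb size filter, a variant is
TE-associated when at least 50% of its span is covered by the merged TE
footprint of the appropriate genome: insertion-like variants are tested
against the genome that gained the sequence, deletion-like variants against
the genome that retains it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

EXPANSION_TYPES = {"insertion", "repeat_expansion", "tandem_expansion"}
CONTRACTION_TYPES = {"deletion", "repeat_contraction", "tandem_contraction"}
KNOWN_TYPES = EXPANSION_TYPES | CONTRACTION_TYPES


@dataclass
class SVRecord:
    variant_id: str
    type: str
    ref_seq: str
    ref_span: tuple[int, int]
    alt_seq: str | None
    alt_span: tuple[int, int] | None
    size: int
    te_associated: bool | None = None
    te_coverage: float | None = None


def records_from_frame(df: pd.DataFrame) -> list[SVRecord]:
    records = []
    has_alt = {"alt_seq", "alt_start", "alt_stop"} <= set(df.columns)
    for row in df.itertuples(index=False):
        alt_seq = getattr(row, "alt_seq", None) if has_alt else None
        records.append(
            SVRecord(
                variant_id=str(row.variant_id),
                type=str(row.type),
                ref_seq=str(row.ref_seq),
                ref_span=(int(row.ref_start), int(row.ref_stop)),
                alt_seq=str(alt_seq) if alt_seq is not None and not pd.isna(alt_seq) else None,
                alt_span=(int(row.alt_start), int(row.alt_stop)) if has_alt and not pd.isna(row.alt_start) else None,
                size=int(row.size),
            )
        )
    return records


def filter_sv(
    records: list[SVRecord], min_size: int = 20, max_size: int = 25_000
) -> list[SVRecord]:
    """Keep variants with min_size <= size <= max_size (both inclusive)."""
    for r in records:
        if r.size < 0:
            raise ValueError(f"{r.variant_id}: negative size")
    return [r for r in records if min_size <= r.size <= max_size]


def _merged_coverage(tree: IntervalTree, span: tuple[int, int]) -> float:
    """Fraction of ``span`` covered by the union of tree intervals."""
    s, e = span
    if e <= s:
        return 0.0
    pieces = sorted((max(s, iv.begin), min(e, iv.end)) for iv in tree.overlap(s, e))
    covered = 0
    cur_s, cur_e = None, None
    for ps, pe in pieces:
        if cur_e is None or ps > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = ps, pe
        else:
            cur_e = max(cur_e, pe)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered / (e - s)


def sv_te_associate(
    records: list[SVRecord],
    te_a: dict[str, list[tuple[int, int]]],
    te_b: dict[str, list[tuple[int, int]]],
    min_te_span: float = 0.5,
    expansion_side: str = "alt",
) -> list[SVRecord]:
    """Flag TE-associated variants by the 50% span rule.

    Insertion/expansion variants are tested against genome A's TE
    annotation over their A-side (``alt``) span; deletion/contraction
    variants against genome B over their B-side (``ref``) span.  Coverage
    is computed on the merged TE footprint, so adding annotations can only
    flag more variants, never fewer.  Unknown variant types pass through
    with ``te_associated=None``.
    """
    trees_a = {k: IntervalTree.from_tuples((s, e) for s, e in v if e > s) for k, v in te_a.items()}
    trees_b = {k: IntervalTree.from_tuples((s, e) for s, e in v if e > s) for k, v in te_b.items()}
    for r in records:
        if r.type not in KNOWN_TYPES:
            r.te_associated = None
            continue
        if r.type in EXPANSION_TYPES:
            if expansion_side == "alt" and r.alt_span is not None and r.alt_seq is not None:
                seq_id, span, trees = r.alt_seq, r.alt_span, trees_a
            else:
                seq_id, span, trees = r.ref_seq, r.ref_span, trees_a
        else:
            seq_id, span, trees = r.ref_seq, r.ref_span, trees_b
        tree = trees.get(seq_id)
        if tree is None:
            if seq_id not in (te_a if trees is trees_a else te_b):
                raise ValueError(f"{r.variant_id}: unknown sequence {seq_id}")
            cov = 0.0
        else:
            cov = _merged_coverage(tree, span)
        r.te_coverage = cov
        r.te_associated = cov >= min_te_span
    return records


def sv_summary(records: list[SVRecord]) -> dict:
    """Counts, Mb and TE-associated counts per variant type."""
    out: dict = {"types": {}, "unknown_types": sorted({r.type for r in records if r.type not in KNOWN_TYPES})}
    for r in records:
        entry = out["types"].setdefault(
            r.type, {"count": 0, "total_bp": 0, "te_associated": 0}
        )
        entry["count"] += 1
        entry["total_bp"] += r.size
        if r.te_associated:
            entry["te_associated"] += 1
    for entry in out["types"].values():
        entry["total_mb"] = entry["total_bp"] / 1e6
        entry["te_associated_pct"] = (
            100.0 * entry["te_associated"] / entry["count"] if entry["count"] else None
        )
    return out


def records_to_frame(records: list[SVRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "type": r.type,
                "ref_seq": r.ref_seq,
                "ref_start": r.ref_span[0],
                "ref_stop": r.ref_span[1],
                "alt_seq": r.alt_seq or "",
                "alt_start": r.alt_span[0] if r.alt_span else "",
                "alt_stop": r.alt_span[1] if r.alt_span else "",
                "size": r.size,
                "te_associated": r.te_associated,
                "te_coverage": r.te_coverage,
            }
            for r in records
        ]
    )
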