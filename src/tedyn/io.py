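"""File I/O: FASTA, GFF3, TSV tables and deletion-call VCFs.

Internal coordinates are 0-based half-open everywhere; GFF3 and VCF are
converted to/from their native 1-based inclusive conventions at the
boundary.
"""

from __future__ import annotations

import re
from pathlib import Path

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    """Write sequences wrapped at 60 columns."""
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def find_n_regions(seq: str, min_len: int = 1) -> list[tuple[int, int]]:
    """Runs of N of at least ``min_len``, as half-open intervals."""
    return [
        (m.start(), m.end())
        for m in re.finditer("N+", seq.upper())
        if m.end() - m.start() >= min_len
    ]


# ---------------------------------------------------------------------------
# LTR element GFF3 / TSV

_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def write_elements_gff3(path: str | Path, elements) -> None:
    """Write LTR elements as GFF3: one ``LTR_retrotransposon`` parent with two
    ``long_terminal_repeat`` children."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for el in elements:
            attrs = (
                f"ID={el.element_id};superfamily={el.superfamily};"
                f"completeness={el.completeness}"
            )
            if el.tsd:
                attrs += f";tsd={el.tsd}"
            fh.write(
                "\t".join(
                    [
                        el.sequence_id, "tedyn", "LTR_retrotransposon",
                        str(el.span[0] + 1), str(el.span[1]), ".", "+", ".", attrs,
                    ]
                )
                + "\n"
            )
            for tag, (s, e) in (("ltr5", el.ltr5_span), ("ltr3", el.ltr3_span)):
                fh.write(
                    "\t".join(
                        [
                            el.sequence_id, "tedyn", "long_terminal_repeat",
                            str(s + 1), str(e),
                            ".", "+", ".",
                            f"ID={el.element_id}_{tag};Parent={el.element_id}",
                        ]
                    )
                    + "\n"
                )


def read_elements_gff3(path: str | Path) -> list:
    """Read LTR elements back from GFF3 (via gffutils, in-memory DB)."""
    from .annotation import LTRElement

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    elements = []
    for feat in db.features_of_type("LTR_retrotransposon"):
        ltrs = sorted(
            (child for child in db.children(feat, featuretype="long_terminal_repeat")),
            key=lambda c: c.start,
        )
        if len(ltrs) != 2:
            raise ValueError(f"element {feat.id} has {len(ltrs)} LTR children, expected 2")
        span = (feat.start - 1, feat.end)
        ltr5 = (ltrs[0].start - 1, ltrs[0].end)
        ltr3 = (ltrs[1].start - 1, ltrs[1].end)
        elements.append(
            LTRElement(
                element_id=feat.id,
                sequence_id=feat.seqid,
                span=span,
                ltr5_span=ltr5,
                ltr3_span=ltr3,
                internal_span=(ltr5[1], ltr3[0]),
                tsd=feat.attributes.get("tsd", [None])[0],
                superfamily=feat.attributes.get("superfamily", ["unclassified"])[0],
                completeness=feat.attributes.get("completeness", ["incomplete"])[0],
            )
        )
    return elements


def elements_to_tsv(path: str | Path, elements) -> None:
    rows = [
        {
            "element_id": el.element_id,
            "sequence_id": el.sequence_id,
            "start": el.span[0],
            "end": el.span[1],
            "ltr5_start": el.ltr5_span[0],
            "ltr5_end": el.ltr5_span[1],
            "ltr3_start": el.ltr3_span[0],
            "ltr3_end": el.ltr3_span[1],
            "superfamily": el.superfamily,
            "completeness": el.completeness,
            "tsd": el.tsd or "",
            "gap_fraction": el.gap_fraction,
            "tandem_fraction": el.tandem_fraction,
        }
        for el in elements
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_domain_tsv(path: str | Path, hits_by_element: dict[str, list]) -> None:
    """Domain-hit table: element_id, domain, start, end, strand (element coords)."""
    rows = [
        {
            "element_id": eid,
            "domain": h.domain,
            "start": h.span_on_element[0],
            "end": h.span_on_element[1],
            "strand": h.strand,
        }
        for eid, hits in hits_by_element.items()
        for h in hits
    ]
    pd.DataFrame(rows, columns=["element_id", "domain", "start", "end", "strand"]).to_csv(
        path, sep="\t", index=False
    )


def read_domain_tsv(path: str | Path) -> dict[str, list]:
    from .annotation import DomainHit

    df = pd.read_csv(path, sep="\t")
    out: dict[str, list] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.element_id, []).append(
            DomainHit(domain=row.domain, span_on_element=(int(row.start), int(row.end)),
                      strand=row.strand)
        )
    return out


# ---------------------------------------------------------------------------
# deletion-call VCF / TSV

_VCF_HEADER_LINES = [
    ('INFO', 'END', '1', 'Integer', 'End position of the deletion (1-based inclusive)'),
    ('INFO', 'SVTYPE', '1', 'String', 'Type of structural variant'),
    ('INFO', 'SVLEN', '1', 'Integer', 'Signed length of the variant'),
    ('INFO', 'SUPPORT', '1', 'Integer', 'Reads supporting the event'),
]


def write_deletions_vcf(path: str | Path, calls, contig_lengths: dict[str, int],
                        sample: str = "sample") -> None:
    """Write deletion calls as an uncompressed VCF (symbolic ``<DEL>`` records).

    POS is the padding base before the event; deleted bases are
    ``[POS, END]`` 1-based inclusive, i.e. the half-open span ``(s, e)``
    maps to POS = s, END = e.
    """
    header = pysam.VariantHeader()
    for rec_type, name, number, vtype, desc in _VCF_HEADER_LINES:
        header.add_meta(
            rec_type, items=[("ID", name), ("Number", number), ("Type", vtype),
                             ("Description", desc)]
        )
    for contig, length in contig_lengths.items():
        header.contigs.add(contig, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: (c.sequence_id, c.span)):
            s, e = call.span
            rec = vcf.new_record(
                contig=call.sequence_id,
                start=max(0, s - 1),  # pysam start is 0-based POS-1
                alleles=("N", "<DEL>"),
                id=f"{sample}_del_{call.sequence_id}_{s}_{e}",
            )
            rec.info["SVTYPE"] = "DEL"
            rec.info["SVLEN"] = -(e - s)
            rec.info["SUPPORT"] = call.support_reads
            rec.stop = e  # set last: INFO assignment resets END
            vcf.write(rec)


def read_deletions_vcf(path: str | Path, cultivar_id: str) -> list:
    """Read deletion calls from a VCF written by this package (or any VCF with
    SVTYPE=DEL, END and a SUPPORT info key)."""
    from .polymorphism import DeletionCall

    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.info.get("SVTYPE") != "DEL":
                continue
            s = rec.pos  # POS (padding base, 1-based) == half-open start
            e = rec.stop
            calls.append(
                DeletionCall(
                    cultivar_id=cultivar_id,
                    sequence_id=rec.chrom,
                    span=(s, e),
                    support_reads=int(rec.info.get("SUPPORT", 0)),
                )
            )
    return calls


def read_deletions_tsv(path: str | Path) -> list:
    """Pindel-like TSV dialect: cultivar_id, sequence_id, start, end, support_reads
    with 0-based half-open coordinates."""
    from .polymorphism import DeletionCall

    df = pd.read_csv(path, sep="\t")
    return [
        DeletionCall(
            cultivar_id=str(row.cultivar_id),
            sequence_id=str(row.sequence_id),
            span=(int(row.start), int(row.end)),
            support_reads=int(row.support_reads),
        )
        for row in df.itertuples(index=False)
    ]


def write_deletions_tsv(path: str | Path, calls) -> None:
    pd.DataFrame(
        [
            {
                "cultivar_id": c.cultivar_id,
                "sequence_id": c.sequence_id,
                "start": c.span[0],
                "end": c.span[1],
                "support_reads": c.support_reads,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def read_te_intervals(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """TE annotation as {sequence_id: [(start, end), ...]} (half-open).

    Accepts BED (0-based half-open) or GFF3 (1-based inclusive; every
    feature line is taken as a TE interval).
    """
    path = Path(path)
    out: dict[str, list[tuple[int, int]]] = {}
    if path.suffix.lower() == ".bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                         names=["seq", "start", "end"])
        for row in df.itertuples(index=False):
            out.setdefault(str(row.seq), []).append((int(row.start), int(row.end)))
        return out
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    for feat in db.all_features():
        if feat.featuretype == "long_terminal_repeat":
            continue  # children of LTR_retrotransposon parents
        out.setdefault(feat.seqid, []).append((feat.start - 1, feat.end))
    return out


# ---------------------------------------------------------------------------
# Assemblytics-style SV table

def read_assemblytics_tsv(path: str | Path) -> pd.DataFrame:
    """Assemblytics-style variant table.

    Required columns: ``variant_id, type, ref_seq, ref_start, ref_stop,
    alt_seq, alt_start, alt_stop, size`` (0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "type", "ref_seq", "ref_start", "ref_stop", "size"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SV table missing columns: {sorted(missing)}")
    return df
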