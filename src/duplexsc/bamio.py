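"""BAM input/output: pairing aligned records and writing consensus streams.

Reads are carried through the pipeline as :class:`PairedRead` objects (both
mates of one template, with the UMI barcode parsed from the query name) so
that grouping and consensus calling operate on plain arrays rather than on
live pysam records.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pysam

#: Reserved delimiter between the original query-name stem and the barcode.
BARCODE_DELIM = "|"


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def split_barcode(qname: str) -> tuple[str, str]:
    """Split a tagged query name into (stem, barcode)."""
    stem, sep, barcode = qname.rpartition(BARCODE_DELIM)
    if not sep:
        return qname, ""
    return stem, barcode


@dataclass
class PairedRead:
    """Both mates of one aligned template with its extracted barcode.

    Sequences are stored as uint8 ASCII arrays in reference orientation
    (as in the BAM); positions are 1-based leftmost mapping positions.
    """

    qname: str
    barcode: str
    contig1: str
    pos1: int
    cigar1: str
    reverse1: bool
    seq1: np.ndarray
    qual1: np.ndarray
    contig2: str
    pos2: int
    cigar2: str
    reverse2: bool
    seq2: np.ndarray
    qual2: np.ndarray


def read_pairs(bam_path: str) -> tuple[list[PairedRead], dict]:
    """Load filtered, paired reads from a BAM.

    Applies the alignment filter (unmapped / mate-unmapped / secondary /
    supplementary), pairs mates by query name, and drops orphans whose mate
    never appears.  Returns the pairs in order of completion plus a counter
    of dropped records by reason.
    """
    from .families import filter_read

    stats = {
        "records": 0,
        "kept_pairs": 0,
        "unmapped": 0,
        "mate-unmapped": 0,
        "multi-alignment": 0,
        "supplementary": 0,
        "orphan": 0,
    }
    pending: dict[str, pysam.AlignedSegment] = {}
    pairs: list[PairedRead] = []
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            stats["records"] += 1
            keep, reason = filter_read(rec)
            if not keep:
                stats[reason] += 1
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            r1, r2 = (mate, rec) if mate.is_read1 else (rec, mate)
            pairs.append(_make_pair(r1, r2))
            stats["kept_pairs"] += 1
    stats["orphan"] = len(pending)
    return pairs, stats


def _make_pair(r1: pysam.AlignedSegment, r2: pysam.AlignedSegment) -> PairedRead:
    stem, barcode = split_barcode(r1.query_name)
    return PairedRead(
        qname=r1.query_name,
        barcode=barcode,
        contig1=r1.reference_name,
        pos1=r1.reference_start + 1,
        cigar1=r1.cigarstring,
        reverse1=r1.is_reverse,
        seq1=seq_to_array(r1.query_sequence),
        qual1=np.asarray(r1.query_qualities, dtype=np.uint8),
        contig2=r2.reference_name,
        pos2=r2.reference_start + 1,
        cigar2=r2.cigarstring,
        reverse2=r2.is_reverse,
        seq2=seq_to_array(r2.query_sequence),
        qual2=np.asarray(r2.query_qualities, dtype=np.uint8),
    )


def make_header(reference_fasta: str) -> pysam.AlignmentHeader:
    """Alignment header whose SQ lines mirror a reference FASTA."""
    import pyfaidx

    fa = pyfaidx.Fasta(reference_fasta)
    sq = [{"SN": name, "LN": len(fa[name])} for name in fa.keys()]
    return pysam.AlignmentHeader.from_dict({"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": sq})


def _segment(header, qname, contig, pos, cigar, reverse, mate_reverse, seq, qual,
             is_read1, mate_contig, mate_pos, tlen) -> pysam.AlignedSegment:
    rec = pysam.AlignedSegment(header=header)
    rec.query_name = qname
    rec.reference_name = contig
    rec.reference_start = pos - 1
    rec.cigarstring = cigar
    rec.query_sequence = seq
    rec.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(q + 33) for q in qual)
    )
    rec.mapping_quality = 60
    flag = 0x1 | 0x2
    flag |= 0x40 if is_read1 else 0x80
    if reverse:
        flag |= 0x10
    if mate_reverse:
        flag |= 0x20
    rec.flag = flag
    rec.next_reference_name = mate_contig
    rec.next_reference_start = mate_pos - 1
    rec.template_length = tlen
    return rec


def consensus_pair_records(cpair, header) -> tuple[pysam.AlignedSegment, pysam.AlignedSegment]:
    """Materialise a consensus pair as two aligned BAM records."""
    key = cpair.key
    rev1 = key.orientation == "rev"
    span1 = _cigar_ref_span(key.cigar1)
    span2 = _cigar_ref_span(key.cigar2)
    left = min(key.pos1, key.pos2)
    right = max(key.pos1 + span1, key.pos2 + span2)
    tlen = right - left
    qname = cpair.pairing_tag()
    r1 = _segment(header, qname, key.contig1, key.pos1, key.cigar1, rev1, not rev1,
                  cpair.r1.sequence(), cpair.r1.qual, True, key.contig2, key.pos2,
                  -tlen if rev1 else tlen)
    r2 = _segment(header, qname, key.contig2, key.pos2, key.cigar2, not rev1, rev1,
                  cpair.r2.sequence(), cpair.r2.qual, False, key.contig1, key.pos1,
                  tlen if rev1 else -tlen)
    return r1, r2


def _cigar_ref_span(cigar: str) -> int:
    span = 0
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            if ch in "MDN=X":
                span += int(n)
            n = ""
    return span


def write_consensus_bam(path: str, cpairs, reference_fasta: str) -> str:
    """Write consensus pairs to a coordinate-sorted, indexed BAM."""
    header = make_header(reference_fasta)
    records = []
    for cp in cpairs:
        records.extend(consensus_pair_records(cp, header))
    return write_records_bam(path, records, header)


def write_records_bam(path: str, records, header) -> str:
    records = sorted(
        records, key=lambda r: (r.reference_id, r.reference_start, r.query_name, r.flag)
    )
    header = _sorted_header(header)
    with pysam.AlignmentFile(path, "wb", header=header) as out:
        for rec in records:
            out.write(rec)
    pysam.index(path)
    return path


def _sorted_header(header: pysam.AlignmentHeader) -> pysam.AlignmentHeader:
    d = header.to_dict()
    d.setdefault("HD", {"VN": "1.6"})["SO"] = "coordinate"
    return pysam.AlignmentHeader.from_dict(d)


def sort_and_index(path: str) -> str:
    tmp = path + ".sorttmp.bam"
    pysam.sort("-o", tmp, path)
    os.replace(tmp, path)
    pysam.index(path)
    return path
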