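"""Extraction of in-line duplex UMIs from raw paired-end FASTQ.

The library design places a 2 bp UMI followed by a single invariant ``T``
spacer at the 5' end of every read.  Extraction removes these first three
bases from each mate, checks the spacer on both mates, and appends the
combined 4 bp barcode (read-1 UMI + read-2 UMI) to the read identifier so
that molecular grouping survives alignment.  Pairs whose spacer base is not
``T`` on either mate are not design-compliant and are discarded.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator

import pysam

from .bamio import BARCODE_DELIM

__all__ = [
    "RawReadPair",
    "TaggedReadPair",
    "Rejected",
    "extract_pair",
    "extract_fastq",
    "write_tagged_fastq",
    "read_fastq_pairs",
]


@dataclass(frozen=True)
class RawReadPair:
    """One paired-end read as it comes off the sequencer."""

    read1_id: str
    read1_seq: str
    read1_qual: str
    read2_id: str
    read2_seq: str
    read2_qual: str

    def __post_init__(self):
        if len(self.read1_seq) != len(self.read1_qual) or len(self.read2_seq) != len(
            self.read2_qual
        ):
            raise ValueError(
                f"sequence/quality length mismatch in read pair {self.read1_id!r}"
            )


@dataclass(frozen=True)
class TaggedReadPair:
    """A read pair with its UMI barcode moved into the identifier stem."""

    id_stem: str
    barcode: str  # 4 characters: read1 UMI + read2 UMI
    read1_seq: str
    read1_qual: str
    read2_seq: str
    read2_qual: str

    @property
    def tagged_id(self) -> str:
        return f"{self.id_stem}{BARCODE_DELIM}{self.barcode}"


@dataclass(frozen=True)
class Rejected:
    """A pair discarded during extraction, with the reason."""

    id_stem: str
    reason: str  # 'spacer' | 'too-short'


def _stem(read_id: str) -> str:
    # strip mate suffix ("/1", "/2") and anything after first whitespace
    stem = read_id.split()[0]
    if stem.endswith("/1") or stem.endswith("/2"):
        stem = stem[:-2]
    return stem


def extract_pair(
    pair: RawReadPair, umi_len: int = 2, spacer: str = "T"
) -> TaggedReadPair | Rejected:
    """Extract the duplex UMI from one read pair.

    The barcode is ``read1[0:umi_len] + read2[0:umi_len]``; the base at
    index ``umi_len`` of *each* mate must equal the invariant spacer, else
    the pair is rejected.  UMI and spacer bases are trimmed from sequence
    and quality.  UMIs containing ``N`` are retained (grouping treats ``N``
    as a literal symbol); UMI base qualities are not checked, quality
    filtering happens at the consensus stage.
    """
    trim = umi_len + 1
    stem = _stem(pair.read1_id)
    if len(pair.read1_seq) < trim + 1 or len(pair.read2_seq) < trim + 1:
        return Rejected(id_stem=stem, reason="too-short")
    if pair.read1_seq[umi_len] != spacer or pair.read2_seq[umi_len] != spacer:
        return Rejected(id_stem=stem, reason="spacer")
    barcode = pair.read1_seq[:umi_len] + pair.read2_seq[:umi_len]
    return TaggedReadPair(
        id_stem=stem,
        barcode=barcode,
        read1_seq=pair.read1_seq[trim:],
        read1_qual=pair.read1_qual[trim:],
        read2_seq=pair.read2_seq[trim:],
        read2_qual=pair.read2_qual[trim:],
    )


def read_fastq_pairs(r1_path: str, r2_path: str) -> Iterator[RawReadPair]:
    """Iterate over mate-synchronised records of two FASTQ files (plain or gzip)."""
    with pysam.FastxFile(r1_path) as f1, pysam.FastxFile(r2_path) as f2:
        for e1, e2 in zip(f1, f2):
            yield RawReadPair(
                read1_id=e1.name,
                read1_seq=e1.sequence,
                read1_qual=e1.quality,
                read2_id=e2.name,
                read2_seq=e2.sequence,
                read2_qual=e2.quality,
            )


def extract_fastq(
    r1_path: str,
    r2_path: str,
    out_r1: str,
    out_r2: str,
    umi_len: int = 2,
    spacer: str = "T",
) -> dict:
    """Run extraction over FASTQ files and write tagged, trimmed output.

    Returns counts of tagged and rejected pairs (by reason).
    """
    counts = {"tagged": 0, "spacer": 0, "too-short": 0}
    tagged = []
    for pair in read_fastq_pairs(r1_path, r2_path):
        result = extract_pair(pair, umi_len=umi_len, spacer=spacer)
        if isinstance(result, Rejected):
            counts[result.reason] += 1
        else:
            counts["tagged"] += 1
            tagged.append(result)
    write_tagged_fastq(tagged, out_r1, out_r2)
    return counts


def _opener(path: str):
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def write_tagged_fastq(pairs: Iterable[TaggedReadPair], out_r1: str, out_r2: str) -> None:
    """Write tagged pairs to two FASTQ files (gzip if the name ends in .gz)."""
    with _opener(out_r1) as f1, _opener(out_r2) as f2:
        for p in pairs:
            f1.write(f"@{p.tagged_id}\n{p.read1_seq}\n+\n{p.read1_qual}\n")
            f2.write(f"@{p.tagged_id}\n{p.read2_seq}\n+\n{p.read2_qual}\n")
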