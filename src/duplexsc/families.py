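"""Molecular identification of read pairs via in-line duplex UMIs.

Each aligned read pair is assigned a :class:`FamilyKey` combining its 4 bp
barcode (2 bp from each fragment end) with genomic position, CIGAR and
orientation.  Pairs sharing a key are PCR duplicates of the same strand of
the same source molecule and form a :class:`ReadFamily`.

The two strands of one double-stranded molecule yield distinct keys that are
related by the *duplex transform*: the barcode halves interchange and the
read numbers switch, because read 1 of the plus strand covers the same
fragment end as read 2 of the minus strand.  Canonicalising a key together
with its transform gives the strand-agnostic :class:`DuplexKey` under which
complementary strands hash together.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "FamilyKey",
    "ReadFamily",
    "duplex_transform",
    "duplex_key",
    "filter_read",
    "family_key",
    "group_pairs",
]

PLUS = "plus"
MINUS = "minus"


@dataclass(frozen=True)
class FamilyKey:
    """Identifier of one strand of one source molecule.

    ``barcode`` is the read-1 UMI half followed by the read-2 UMI half.
    Positions are 1-based leftmost mapping positions as recorded in the
    alignment; soft clips are not unwound because CIGAR is itself part of
    the key and already separates clip variants.  ``orientation`` is the
    mapping orientation of read 1 (``fwd``/``rev``); read number is encoded
    positionally by the 1/2 slots.
    """

    barcode: str
    contig1: str
    pos1: int
    cigar1: str
    contig2: str
    pos2: int
    cigar2: str
    orientation: str  # 'fwd' | 'rev', orientation of read 1

    @property
    def strand(self) -> str:
        """Strand of origin: R1-forward pairs derive from the plus strand."""
        return PLUS if self.orientation == "fwd" else MINUS

    def serialize(self) -> str:
        return (
            f"{self.barcode}:{self.contig1}:{self.pos1}:{self.cigar1}"
            f":{self.contig2}:{self.pos2}:{self.cigar2}:{self.orientation}"
        )


def duplex_transform(key: FamilyKey) -> FamilyKey:
    """Key of the complementary strand of the same molecule.

    Barcode halves interchange (AC/GT on the plus strand pairs with GT/AC
    on the minus strand), the read-number slots swap, and the orientation
    flips.  The transform is an involution.
    """
    flip = "rev" if key.orientation == "fwd" else "fwd"
    return FamilyKey(
        barcode=key.barcode[2:] + key.barcode[:2],
        contig1=key.contig2,
        pos1=key.pos2,
        cigar1=key.cigar2,
        contig2=key.contig1,
        pos2=key.pos1,
        cigar2=key.cigar1,
        orientation=flip,
    )


def duplex_key(key: FamilyKey) -> str:
    """Strand-canonical molecule identifier.

    The lexicographic minimum of the serialized key and its duplex
    transform; symmetric by construction, so both strands of a molecule
    map to the same value.
    """
    a = key.serialize()
    b = duplex_transform(key).serialize()
    return a if a <= b else b


def filter_read(record) -> tuple[bool, str | None]:
    """Alignment-level read filter applied before family grouping.

    Drops reads that are unmapped, paired with an unmapped mate, or are
    secondary/supplementary alignments.  Returns ``(keep, reason)``.
    """
    if record.is_unmapped:
        return False, "unmapped"
    if record.mate_is_unmapped:
        return False, "mate-unmapped"
    if record.is_secondary:
        return False, "multi-alignment"
    if record.is_supplementary:
        return False, "supplementary"
    return True, None


def family_key(pair) -> FamilyKey:
    """Build the FamilyKey of an aligned, barcode-tagged read pair."""
    if not pair.barcode:
        raise ValueError(
            f"read pair {pair.qname!r} carries no barcode; UMI extraction "
            "must run before family grouping"
        )
    return FamilyKey(
        barcode=pair.barcode,
        contig1=pair.contig1,
        pos1=pair.pos1,
        cigar1=pair.cigar1,
        contig2=pair.contig2,
        pos2=pair.pos2,
        cigar2=pair.cigar2,
        orientation="rev" if pair.reverse1 else "fwd",
    )


@dataclass
class ReadFamily:
    """All read pairs sharing one FamilyKey (PCR duplicates of one strand)."""

    key: FamilyKey
    members: list

    @property
    def size(self) -> int:
        return len(self.members)


def group_pairs(pairs: Iterable) -> list[ReadFamily]:
    """Partition read pairs into families by exact FamilyKey match.

    Deterministic and order-preserving: families appear in order of first
    member, members in input order.
    """
    by_key: dict[FamilyKey, ReadFamily] = {}
    for pair in pairs:
        key = family_key(pair)
        fam = by_key.get(key)
        if fam is None:
            by_key[key] = ReadFamily(key=key, members=[pair])
        else:
            fam.members.append(pair)
    return list(by_key.values())
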