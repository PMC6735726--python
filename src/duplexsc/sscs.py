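"""Single-strand consensus calling.

Families with two or more members are collapsed into single-strand
consensus sequences (SSCS): at each position, bases below the Phred
threshold (default Q30) are discarded, and the most frequent surviving base
is called if its proportion among survivors reaches the consensus cutoff
(default 0.7), otherwise ``N``.  Size-1 families are singletons and are
routed to the singleton stream for possible rescue by the complementary
strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .bamio import PairedRead, array_to_seq
from .families import FamilyKey, ReadFamily

__all__ = [
    "ConsensusConfig",
    "ConsensusRead",
    "ConsensusPair",
    "consensus_base",
    "collapse_family",
    "route_families",
    "singleton_pair",
]

# provenance labels
SSCS = "SSCS"
SC_BY_SSCS = "SC_by_SSCS"
SC_BY_SINGLETON = "SC_by_singleton"
DCS = "DCS"
UNCORRECTED = "uncorrected_singleton"

_N = ord("N")
_BASE_CODES = np.frombuffer(b"ACGTN", dtype=np.uint8)


@dataclass(frozen=True)
class ConsensusConfig:
    """Tunable thresholds of consensus formation.

    ``min_base_quality``: only bases at or above this Phred score take part
    in consensus evaluation.  ``consensus_cutoff``: minimum proportion of
    surviving reads that must agree for a base call; must exceed 0.5 so the
    winning base is unique.
    """

    min_base_quality: int = 30
    consensus_cutoff: float = 0.7

    def __post_init__(self):
        if not (0.5 < self.consensus_cutoff <= 1.0):
            raise ValueError("consensus_cutoff must be in (0.5, 1.0]")
        if self.min_base_quality < 0:
            raise ValueError("min_base_quality must be non-negative")


@dataclass
class ConsensusRead:
    """One error-suppressed read (half of a consensus pair)."""

    seq: np.ndarray  # uint8 ASCII codes, 'N' allowed
    qual: np.ndarray  # Phred scores, 0 at N positions

    def sequence(self) -> str:
        return array_to_seq(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ConsensusPair:
    """An error-suppressed read pair with family-size and provenance metadata."""

    key: FamilyKey
    r1: ConsensusRead
    r2: ConsensusRead
    provenance: str
    family_size: int

    def pairing_tag(self) -> str:
        """Consensus query name: barcode plus coordinate-ordered mapping,
        strand of origin, strand/read-number-ordered CIGARs, and family size."""
        k = self.key
        coords = sorted([(k.contig1, k.pos1), (k.contig2, k.pos2)])
        loc = ";".join(f"{c}:{p}" for c, p in coords)
        return (
            f"{k.barcode}{BARCODE_SEP}{loc}{BARCODE_SEP}{k.strand}"
            f"{BARCODE_SEP}{k.cigar1}.{k.cigar2}{BARCODE_SEP}fs{self.family_size}"
        )


BARCODE_SEP = "_"


def consensus_base(
    column: Sequence[tuple[str, int]], cfg: ConsensusConfig = ConsensusConfig()
) -> str:
    """Consensus call for one aligned position of one read family.

    ``column`` holds (base, quality) observations.  Bases below the quality
    threshold are removed first; among survivors the most common base is
    assigned iff its proportion is >= the cutoff, otherwise ``N``.  An empty
    survivor set yields ``N``.
    """
    survivors = [b for b, q in column if q >= cfg.min_base_quality and b != "N"]
    if not survivors:
        return "N"
    best, count = "", 0
    for b in "ACGT":
        c = survivors.count(b)
        if c > count:
            best, count = b, c
    if count / len(survivors) >= cfg.consensus_cutoff:
        return best
    return "N"


def _collapse_columns(
    seqs: np.ndarray, quals: np.ndarray, cfg: ConsensusConfig
) -> ConsensusRead:
    """Vectorised per-position consensus over a (members x length) stack."""
    valid = (quals >= cfg.min_base_quality) & (seqs != _N)
    counts = np.stack([((seqs == code) & valid).sum(axis=0) for code in _BASE_CODES[:4]])
    totals = valid.sum(axis=0)
    winner = counts.argmax(axis=0)
    top = counts.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        called = (totals > 0) & (top >= cfg.consensus_cutoff * totals)
    seq = np.where(called, _BASE_CODES[winner], _N).astype(np.uint8)
    # consensus quality: max quality among reads agreeing with the call
    agree = valid & (seqs == seq[None, :])
    qual = np.where(agree, quals, 0).max(axis=0).astype(np.uint8)
    qual[seq == _N] = 0
    return ConsensusRead(seq=seq, qual=qual)


def collapse_family(
    family: ReadFamily, cfg: ConsensusConfig = ConsensusConfig()
) -> ConsensusPair:
    """Collapse a read family of size >= 2 into an SSCS pair.

    Members share CIGAR and position (guaranteed by the key), so columns
    are paired by read offset with no realignment.
    """
    if family.size < 2:
        raise ValueError("collapse_family requires a family of size >= 2; "
                         "route size-1 families to the singleton stream")
    members: list[PairedRead] = family.members
    r1 = _collapse_columns(
        np.stack([m.seq1 for m in members]),
        np.stack([m.qual1 for m in members]),
        cfg,
    )
    r2 = _collapse_columns(
        np.stack([m.seq2 for m in members]),
        np.stack([m.qual2 for m in members]),
        cfg,
    )
    return ConsensusPair(
        key=family.key, r1=r1, r2=r2, provenance=SSCS, family_size=family.size
    )


def singleton_pair(family: ReadFamily) -> ConsensusPair:
    """Wrap a size-1 family as an (uncorrected) singleton consensus pair."""
    if family.size != 1:
        raise ValueError("singleton_pair requires a family of size 1")
    m: PairedRead = family.members[0]
    return ConsensusPair(
        key=family.key,
        r1=ConsensusRead(seq=m.seq1.copy(), qual=m.qual1.copy()),
        r2=ConsensusRead(seq=m.seq2.copy(), qual=m.qual2.copy()),
        provenance=UNCORRECTED,
        family_size=1,
    )


def route_families(
    families: Iterable[ReadFamily],
) -> tuple[list[ReadFamily], list[ReadFamily]]:
    """Partition families into (collapsible, singleton) by size."""
    collapsible, singletons = [], []
    for fam in families:
        (collapsible if fam.size >= 2 else singletons).append(fam)
    return collapsible, singletons
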