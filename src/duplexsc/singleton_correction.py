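"""Singleton Correction: rescuing single reads with the complementary strand.

Traditional UMI consensus discards molecules represented by a single read
pair per strand.  Because the two strands of one molecule hash together
under the duplex key, a singleton can instead be cross-checked against the
complementary strand: first against a complementary SSCS (*SC by SSCS*),
and failing that against the complementary singleton (*SC by singletons*).
Concordant bases are retained, mismatches and sub-Q30 bases become ``N``.
This removes independent polymerase/sequencer errors and strand-asymmetric
damage (e.g. oxidative G>T lesions) while keeping the molecule available
for duplex consensus formation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .families import duplex_key, duplex_transform
from .sscs import (
    SC_BY_SINGLETON,
    SC_BY_SSCS,
    SSCS,
    ConsensusConfig,
    ConsensusPair,
    ConsensusRead,
)

__all__ = [
    "correct_by_sscs",
    "correct_by_singleton",
    "run_singleton_correction",
    "SCResult",
]

_N = ord("N")


def _concordance(a: ConsensusRead, b: ConsensusRead, cfg: ConsensusConfig) -> ConsensusRead:
    """Cross-strand per-position consensus of two reads covering the same
    reference segment (both stored in reference orientation).

    A base survives only when both observations pass the quality filter and
    agree; otherwise the position becomes ``N`` with quality 0.  Kept bases
    take the minimum of the two contributing qualities.
    """
    if len(a) != len(b):
        raise ValueError("complementary reads must cover identical segments")
    ok = (
        (a.seq == b.seq)
        & (a.seq != _N)
        & (a.qual >= cfg.min_base_quality)
        & (b.qual >= cfg.min_base_quality)
    )
    seq = np.where(ok, a.seq, _N).astype(np.uint8)
    qual = np.where(ok, np.minimum(a.qual, b.qual), 0).astype(np.uint8)
    return ConsensusRead(seq=seq, qual=qual)


def _check_complementary(a: ConsensusPair, b: ConsensusPair) -> None:
    if b.key != duplex_transform(a.key):
        raise ValueError(
            f"reads are not complementary strands of one molecule: "
            f"{a.key.serialize()} vs {b.key.serialize()}"
        )


def _corrected(target: ConsensusPair, partner: ConsensusPair,
               cfg: ConsensusConfig, provenance: str) -> ConsensusPair:
    # partner's read numbers are switched relative to target: its R2 covers
    # the same fragment end (and reference segment) as target's R1.
    return ConsensusPair(
        key=target.key,
        r1=_concordance(target.r1, partner.r2, cfg),
        r2=_concordance(target.r2, partner.r1, cfg),
        provenance=provenance,
        family_size=1,
    )


def correct_by_sscs(
    singleton: ConsensusPair,
    sscs: ConsensusPair,
    cfg: ConsensusConfig = ConsensusConfig(),
) -> ConsensusPair:
    """Correct a singleton against the SSCS of the complementary strand.

    The SSCS itself is not modified; it proceeds to duplex formation with
    the corrected singleton as its partner.
    """
    _check_complementary(singleton, sscs)
    return _corrected(singleton, sscs, cfg, SC_BY_SSCS)


def correct_by_singleton(
    s1: ConsensusPair,
    s2: ConsensusPair,
    cfg: ConsensusConfig = ConsensusConfig(),
) -> tuple[ConsensusPair, ConsensusPair]:
    """Correct two complementary singletons against each other.

    Both corrected reads are emitted, one per strand, so downstream duplex
    pairing sees both.  The operation is symmetric: swapping the arguments
    mirrors the outputs.
    """
    _check_complementary(s1, s2)
    return (
        _corrected(s1, s2, cfg, SC_BY_SINGLETON),
        _corrected(s2, s1, cfg, SC_BY_SINGLETON),
    )


@dataclass
class SCResult:
    """Disjoint output streams of singleton correction."""

    by_sscs: list = field(default_factory=list)
    by_singleton: list = field(default_factory=list)
    uncorrected: list = field(default_factory=list)

    @property
    def corrected(self) -> list:
        return self.by_sscs + self.by_singleton


def run_singleton_correction(
    singletons: list[ConsensusPair],
    sscs_list: list[ConsensusPair],
    cfg: ConsensusConfig = ConsensusConfig(),
) -> SCResult:
    """Step-wise singleton correction over keyed streams.

    Priority is SC-by-SSCS over SC-by-singletons; each singleton is consumed
    at most once.  Conservation: ``|by_sscs| + |by_singleton| + |uncorrected|
    == |singletons|`` (each by-singleton event consumes two inputs and emits
    two corrected reads).
    """
    sscs_by_dk: dict[str, list[ConsensusPair]] = {}
    for s in sscs_list:
        assert s.provenance == SSCS
        sscs_by_dk.setdefault(duplex_key(s.key), []).append(s)

    singleton_by_key = {}
    for s in singletons:
        # two singletons with one FamilyKey would have been a family
        assert s.key not in singleton_by_key, "duplicate FamilyKey among singletons"
        singleton_by_key[s.key] = s

    result = SCResult()
    consumed: set = set()
    for s in singletons:
        if s.key in consumed:
            continue
        dk = duplex_key(s.key)
        partner_keys = [p for p in sscs_by_dk.get(dk, []) if p.key != s.key]
        if partner_keys:
            assert len(partner_keys) == 1, "more than one complementary SSCS"
            result.by_sscs.append(correct_by_sscs(s, partner_keys[0], cfg))
            consumed.add(s.key)
            continue
        mate = singleton_by_key.get(duplex_transform(s.key))
        if mate is not None:
            c1, c2 = correct_by_singleton(s, mate, cfg)
            result.by_singleton.extend([c1, c2])
            consumed.add(s.key)
            consumed.add(mate.key)
            continue
        result.uncorrected.append(s)
        consumed.add(s.key)
    return result
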