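"""Duplex consensus formation and the all-unique-molecules output.

A duplex consensus sequence (DCS) condenses the two strand consensuses
(SSCS or corrected singletons) of one molecule: matched bases are
preserved, mismatches become ``N``.  Because a lesion such as 8-oxoguanine
sits on only one strand, this second layer eliminates strand-asymmetric
artefacts.  Molecules whose second strand was never sequenced remain as
unpaired SSCS; together with uncorrected singletons and DCS they form the
"all unique molecules" file in which every template is represented once.
"""

from __future__ import annotations

import numpy as np

from .families import duplex_key, duplex_transform
from .sscs import DCS, ConsensusPair, ConsensusRead

__all__ = ["form_dcs", "pair_strands", "merge_all_unique"]

_N = ord("N")


def _matched(a: ConsensusRead, b: ConsensusRead) -> ConsensusRead:
    if len(a) != len(b):
        raise ValueError("strand consensuses must cover identical segments")
    ok = (a.seq == b.seq) & (a.seq != _N)
    seq = np.where(ok, a.seq, _N).astype(np.uint8)
    qual = np.where(ok, np.maximum(a.qual, b.qual), 0).astype(np.uint8)
    return ConsensusRead(seq=seq, qual=qual)


def form_dcs(a: ConsensusPair, b: ConsensusPair) -> ConsensusPair:
    """Duplex consensus of two complementary strand consensuses.

    Emitted in the canonical key orientation (the strand whose serialized
    key is the duplex key), so repeated runs are byte-stable regardless of
    input order.  Family size is the sum of the contributing sizes.
    """
    if b.key != duplex_transform(a.key):
        raise ValueError("form_dcs requires complementary strand consensuses")
    canon, other = (a, b) if a.key.serialize() <= b.key.serialize() else (b, a)
    return ConsensusPair(
        key=canon.key,
        r1=_matched(canon.r1, other.r2),
        r2=_matched(canon.r2, other.r1),
        provenance=DCS,
        family_size=a.family_size + b.family_size,
    )


def pair_strands(
    consensuses: list[ConsensusPair],
) -> tuple[list[ConsensusPair], list[ConsensusPair]]:
    """Match complementary strand consensuses into DCS.

    Input is the merged SSCS(+corrected singleton) stream.  Within each
    duplex key at most two strand consensuses can exist (one per strand);
    pairs form a DCS, leftovers go to the unpaired stream.
    """
    by_dk: dict[str, list[ConsensusPair]] = {}
    for c in consensuses:
        by_dk.setdefault(duplex_key(c.key), []).append(c)
    dcs, unpaired = [], []
    for dk, group in by_dk.items():
        assert len(group) <= 2, f"more than two strand consensuses under duplex key {dk}"
        if len(group) == 2:
            dcs.append(form_dcs(group[0], group[1]))
        else:
            unpaired.append(group[0])
    return dcs, unpaired


def merge_all_unique(
    dcs: list[ConsensusPair],
    unpaired_sscs: list[ConsensusPair],
    uncorrected_singletons: list[ConsensusPair],
) -> list[ConsensusPair]:
    """Combine DCS, unpaired SSCS and uncorrected singletons.

    Each template molecule is represented at most once; a duplex key seen
    in two streams is a pipeline error.
    """
    merged: list[ConsensusPair] = []
    seen: dict[str, str] = {}
    for stream_name, stream in (
        ("DCS", dcs),
        ("unpaired_SSCS", unpaired_sscs),
        ("uncorrected_singletons", uncorrected_singletons),
    ):
        for c in stream:
            dk = duplex_key(c.key)
            if dk in seen:
                raise ValueError(
                    f"molecule {dk} appears in both {seen[dk]} and {stream_name}"
                )
            seen[dk] = stream_name
            merged.append(c)
    return merged
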