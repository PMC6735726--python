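"""Coverage, efficiency/recovery, and background-error profiling.

Depth is *fragment* coverage: at every panel position, distinct templates
are counted once even where mates overlap, so consensus and raw files are
compared in molecule units.  Efficiency relates consensus coverage to
uncollapsed coverage (an efficiency of 10% means ten reads were spent per
consensus sequence); DCS recovery compares observed duplex coverage with
its theoretical maximum of half the SSCS coverage.  The error report
tallies non-reference bases below an allele-frequency ceiling (default 5%,
above which a locus is treated as a real variant) over all sequenced bases
in the panel, broken into the twelve substitution classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
import pyfaidx

__all__ = [
    "read_panel",
    "fragment_coverage",
    "efficiency",
    "dcs_recovery",
    "error_report",
    "gt_ca_imbalance",
    "CoverageReport",
    "ErrorReport",
    "SUBSTITUTION_CLASSES",
]

SUBSTITUTION_CLASSES = [
    f"{r}>{o}" for r in "ACGT" for o in "ACGT" if r != o
]


def read_panel(bed_path: str) -> pd.DataFrame:
    """Load a target panel from BED (0-based half-open intervals)."""
    panel = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["contig", "start", "end"],
        dtype={"contig": str},
    )
    if panel.empty:
        raise ValueError(f"panel {bed_path!r} contains no intervals")
    return panel


def _check_contigs(bam: pysam.AlignmentFile, panel: pd.DataFrame, source: str) -> None:
    missing = sorted(set(panel["contig"]) - set(bam.references))
    if missing:
        raise ValueError(f"panel contigs absent from {source}: {missing}")


def fragment_coverage(bam_path: str, bed_path: str) -> float:
    """Mean fragment depth over the panel.

    Per position, distinct templates with at least one aligned base are
    counted (overlapping mates count once).  The mean runs over *all* panel
    positions, including zero-depth ones.
    """
    panel = read_panel(bed_path)
    total, positions = 0.0, 0
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        _check_contigs(bam, panel, bam_path)
        for row in panel.itertuples():
            length = row.end - row.start
            diff = np.zeros(length + 1, dtype=np.int64)
            # union of aligned blocks per template, clipped to the interval
            blocks: dict[str, list[tuple[int, int]]] = {}
            for rec in bam.fetch(row.contig, row.start, row.end):
                if rec.is_unmapped:
                    continue
                blocks.setdefault(rec.query_name, []).extend(rec.get_blocks())
            for spans in blocks.values():
                for s, e in _merge_spans(spans):
                    s = max(s, row.start) - row.start
                    e = min(e, row.end) - row.start
                    if s < e:
                        diff[s] += 1
                        diff[e] -= 1
            total += np.cumsum(diff[:-1]).sum()
            positions += length
    return total / positions


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    spans = sorted(spans)
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def efficiency(cov_consensus: float, cov_uncollapsed: float) -> float | None:
    """Consensus sequences produced per sequenced read (coverage ratio)."""
    if cov_uncollapsed <= 0:
        return None
    return cov_consensus / cov_uncollapsed


def dcs_recovery(cov_dcs: float, cov_sscs: float) -> float | None:
    """Observed DCS coverage over its expectation of half the SSCS coverage."""
    if cov_sscs <= 0:
        return None
    return cov_dcs / (cov_sscs / 2.0)


@dataclass
class CoverageReport:
    """Fragment depths and the efficiency/recovery ratios derived from them."""

    cov_uncollapsed: float
    cov_sscs: float
    cov_dcs: float
    efficiency_sscs: float | None = None
    efficiency_dcs: float | None = None
    recovery_dcs: float | None = None

    def __post_init__(self):
        if self.efficiency_sscs is None:
            self.efficiency_sscs = efficiency(self.cov_sscs, self.cov_uncollapsed)
        if self.efficiency_dcs is None:
            self.efficiency_dcs = efficiency(self.cov_dcs, self.cov_uncollapsed)
        if self.recovery_dcs is None:
            self.recovery_dcs = dcs_recovery(self.cov_dcs, self.cov_sscs)


@dataclass
class ErrorReport:
    """Selector-wide background error rate with 12-class substitution profile."""

    error_rate: float
    substitution_counts: dict[str, int]
    error_free_positions: float
    total_bases: int
    nonref_bases: int
    af_ceiling: float = 0.05

    def per_position_table(self) -> pd.DataFrame | None:
        return self._table

    _table: pd.DataFrame | None = field(default=None, repr=False, compare=False)


def error_report(
    bam_path: str,
    reference_fasta: str,
    bed_path: str,
    af_ceiling: float = 0.05,
    keep_table: bool = False,
) -> ErrorReport:
    """Background error profile of a BAM over the target panel.

    Per panel position the A/C/G/T observations are tallied (``N`` bases
    are excluded from numerator and denominator).  A non-reference allele
    whose frequency is below ``af_ceiling`` counts as error; at or above
    the ceiling it is treated as a putative variant and excluded from the
    error numerator for that allele only.  The result is invariant to BAM
    record order.
    """
    panel = read_panel(bed_path)
    ref = pyfaidx.Fasta(reference_fasta)
    missing = sorted(set(panel["contig"]) - set(ref.keys()))
    if missing:
        raise ValueError(f"panel contigs absent from reference: {missing}")

    base_index = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        base_index[b] = i

    total = 0
    nonref = 0
    sub_counts = {cls: 0 for cls in SUBSTITUTION_CLASSES}
    covered_positions = 0
    clean_positions = 0
    rows = []

    with pysam.AlignmentFile(bam_path, "rb") as bam:
        _check_contigs(bam, panel, bam_path)
        for row in panel.itertuples():
            length = row.end - row.start
            counts = np.zeros((4, length), dtype=np.int64)
            for rec in bam.fetch(row.contig, row.start, row.end):
                seq = rec.query_sequence
                if seq is None:
                    continue
                codes = base_index[np.frombuffer(seq.encode(), dtype=np.uint8)]
                for qstart, rstart, ln in _aligned_blocks(rec):
                    s = max(rstart, row.start)
                    e = min(rstart + ln, row.end)
                    if s >= e:
                        continue
                    block = codes[qstart + (s - rstart): qstart + (e - rstart)]
                    ok = block >= 0
                    np.add.at(counts, (block[ok], np.arange(s, e)[ok] - row.start), 1)
            ref_seq = str(ref[row.contig][row.start:row.end]).upper()
            ref_codes = base_index[np.frombuffer(ref_seq.encode(), dtype=np.uint8)]
            depth = counts.sum(axis=0)
            covered = depth > 0
            covered_positions += int(covered.sum())
            total += int(depth.sum())
            pos_nonref = np.zeros(length, dtype=np.int64)
            for code in range(4):
                at_ref = ref_codes == code
                pos_nonref[at_ref] += depth[at_ref] - counts[code, at_ref]
            clean_positions += int((covered & (pos_nonref == 0)).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                af = counts / np.where(depth > 0, depth, 1)
            for code in range(4):
                is_err = (
                    (ref_codes != code)
                    & (ref_codes >= 0)
                    & (counts[code] > 0)
                    & (af[code] < af_ceiling)
                )
                idx = np.nonzero(is_err)[0]
                for i in idx:
                    cls = f"{'ACGT'[ref_codes[i]]}>{'ACGT'[code]}"
                    sub_counts[cls] += int(counts[code, i])
                    nonref += int(counts[code, i])
            if keep_table:
                rows.append(
                    pd.DataFrame(
                        {
                            "contig": row.contig,
                            "pos": np.arange(row.start, row.end) + 1,
                            "ref": list(ref_seq),
                            "A": counts[0],
                            "C": counts[1],
                            "G": counts[2],
                            "T": counts[3],
                        }
                    )
                )

    report = ErrorReport(
        error_rate=nonref / total if total else 0.0,
        substitution_counts=sub_counts,
        error_free_positions=(clean_positions / covered_positions)
        if covered_positions
        else 1.0,
        total_bases=total,
        nonref_bases=nonref,
        af_ceiling=af_ceiling,
    )
    if keep_table:
        report._table = pd.concat(rows, ignore_index=True)
    return report


def _aligned_blocks(rec: pysam.AlignedSegment):
    """(query_offset, ref_pos, length) for each aligned (M/=/X) cigar run."""
    qpos, rpos = 0, rec.reference_start
    for op, ln in rec.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            yield qpos, rpos, ln
            qpos += ln
            rpos += ln
        elif op in (1, 4):  # I, S consume query
            qpos += ln
        elif op in (2, 3):  # D, N consume reference
            rpos += ln
    # H and P consume neither


def gt_ca_imbalance(report: ErrorReport, pseudocount: float = 0.5) -> float:
    """Ratio of G>T to C>A error counts, the oxidative-damage signature.

    A small pseudocount keeps the statistic defined when either class is
    empty; a clean profile gives a value near 1.
    """
    gt = report.substitution_counts["G>T"]
    ca = report.substitution_counts["C>A"]
    return (gt + pseudocount) / (ca + pseudocount)
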