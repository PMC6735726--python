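"""Ground-truth simulator for duplex-UMI libraries.

Emulates the library design end to end: double-stranded fragments drawn
from a target panel, a 2 bp UMI plus invariant ``T`` spacer on each
fragment end, per-strand PCR duplicate counts, independent per-base
substitution errors, and strand-asymmetric oxidative G>T lesions.  Output
is raw FASTQ (UMI layout intact), a truth-aligned coordinate-sorted BAM
(coordinates taken from the truth, bypassing an aligner so tests are free
of aligner nondeterminism), and a molecule-level truth table.

Per-strand read-count distributions are given as compact spec strings:

``fixed:k``
    every strand sequenced exactly k times;
``poisson:lam``
    independent Poisson counts (strands may drop out entirely);
``ztpoisson:lam``
    zero-truncated Poisson, every strand seen at least once;
``mixpoisson:lam_hi,lam_lo,w_lo``
    molecule-level mixture: a fraction ``w_lo`` of molecules amplify
    poorly (both strands Poisson(lam_lo)), the rest amplify well.  The
    shared factor couples the two strands of a molecule, which is what
    makes the singleton-correction rate depth-dependent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bamio import BARCODE_DELIM, make_header, write_records_bam, _segment

__all__ = [
    "SimConfig",
    "CountDistribution",
    "parse_count_dist",
    "simulate_library",
    "expected_stream_sizes",
    "write_toy_reference",
    "write_toy_panel",
    "SimResult",
]

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {65: 84, 67: 71, 71: 67, 84: 65}  # A<->T, C<->G


# ---------------------------------------------------------------------------
# read-count distributions

class CountDistribution:
    """Per-strand read-count law, possibly coupled between strands.

    Represented as a molecule-level mixture of components; within one
    component the two strand counts are independent and identically
    distributed.
    """

    def __init__(self, spec: str, components: list[tuple[float, str, float]]):
        self.spec = spec
        self.components = components  # (weight, kind, param)

    def sample(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Draw (plus, minus) read counts for n molecules."""
        weights = np.array([w for w, _, _ in self.components])
        choice = rng.choice(len(self.components), size=n, p=weights / weights.sum())
        plus = np.zeros(n, dtype=np.int64)
        minus = np.zeros(n, dtype=np.int64)
        for ci, (_, kind, lam) in enumerate(self.components):
            idx = np.nonzero(choice == ci)[0]
            if idx.size == 0:
                continue
            plus[idx] = _draw(rng, kind, lam, idx.size)
            minus[idx] = _draw(rng, kind, lam, idx.size)
        return plus, minus

    def strand_probs(self) -> list[tuple[float, np.ndarray]]:
        """Per component: (weight, [P(0), P(1), P(>=2)]) for one strand."""
        out = []
        for w, kind, lam in self.components:
            if kind == "fixed":
                k = int(lam)
                p = np.array([k == 0, k == 1, k >= 2], dtype=float)
            elif kind == "poisson":
                p0 = math.exp(-lam)
                p1 = lam * p0
                p = np.array([p0, p1, 1.0 - p0 - p1])
            elif kind == "ztpoisson":
                z = 1.0 - math.exp(-lam)
                p1 = lam * math.exp(-lam) / z
                p = np.array([0.0, p1, 1.0 - p1])
            else:  # pragma: no cover
                raise ValueError(kind)
            out.append((w, p))
        return out

    def pattern_probs(self) -> np.ndarray:
        """3x3 matrix of strand-pattern probabilities over {0, 1, >=2}^2."""
        m = np.zeros((3, 3))
        for w, p in self.strand_probs():
            m += w * np.outer(p, p)
        return m


def _draw(rng, kind, lam, size):
    if kind == "fixed":
        return np.full(size, int(lam), dtype=np.int64)
    if kind == "poisson":
        return rng.poisson(lam, size=size)
    if kind == "ztpoisson":
        out = rng.poisson(lam, size=size)
        while True:
            zero = out == 0
            if not zero.any():
                return out
            out[zero] = rng.poisson(lam, size=int(zero.sum()))
    raise ValueError(kind)


def parse_count_dist(spec: str) -> CountDistribution:
    kind, _, rest = spec.partition(":")
    if kind in ("fixed", "poisson", "ztpoisson"):
        return CountDistribution(spec, [(1.0, kind, float(rest))])
    if kind == "mixpoisson":
        lam_hi, lam_lo, w_lo = (float(x) for x in rest.split(","))
        return CountDistribution(
            spec, [(w_lo, "poisson", lam_lo), (1.0 - w_lo, "poisson", lam_hi)]
        )
    raise ValueError(f"unknown count distribution spec {spec!r}")


# ---------------------------------------------------------------------------
# configuration

@dataclass
class SimConfig:
    """Study conditions of one simulated library.

    Defaults mirror a hybrid-capture duplex library: ~200 bp fragments
    (median insert 180-250 bp), 100 bp paired-end reads, 2+2 bp UMIs with a
    ``T`` spacer, and base qualities drawn from a two-point Q37/Q25 mixture
    so the Q30 consensus filter is exercised through ``frac_below_q30``.
    """

    reference: str = ""
    panel: str = ""
    n_molecules: int = 1000
    fragment_mean: float = 200.0
    fragment_sd: float = 30.0
    fragment_min: int = 50
    read_length: int = 100
    umi_len: int = 2
    spacer: str = "T"
    per_strand_reads: str = "ztpoisson:1.2"
    seq_error_rate: float = 0.0
    oxidation_rate: float = 0.0
    quality_high: int = 37
    quality_low: int = 25
    frac_below_q30: float = 0.0
    n_spacer_fail: int = 0
    seed: int = 0


@dataclass
class SimResult:
    """Paths and in-memory truth of one simulated library."""

    bam: str | None
    fastq_r1: str | None
    fastq_r2: str | None
    truth_path: str | None
    truth: pd.DataFrame
    config: SimConfig
    n_reads: int


# ---------------------------------------------------------------------------
# toy reference and panel

def write_toy_reference(
    path: str, n_contigs: int = 2, contig_length: int = 25000, seed: int = 7
) -> str:
    """Write a deterministic random toy genome (~50 kb by default)."""
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        for c in range(n_contigs):
            seq = _CODE_TO_BASE[rng.integers(0, 4, size=contig_length)].tobytes().decode()
            fh.write(f">toy{c + 1}\n")
            for i in range(0, contig_length, 60):
                fh.write(seq[i: i + 60] + "\n")
    import pyfaidx

    pyfaidx.Fasta(path)  # build .fai alongside
    return path


def write_toy_panel(path: str, reference: str, margin: int = 500) -> str:
    """Target panel covering each contig minus a placement margin."""
    import pyfaidx

    fa = pyfaidx.Fasta(reference)
    with open(path, "w") as fh:
        for name in fa.keys():
            fh.write(f"{name}\t{margin}\t{len(fa[name]) - margin}\n")
    return path


# ---------------------------------------------------------------------------
# library simulation

def simulate_library(
    cfg: SimConfig,
    out_dir: str,
    write_bam: bool = True,
    write_fastq: bool = False,
) -> SimResult:
    """Generate a duplex-UMI library with complete ground truth.

    Deterministic given the config (identical config incl. seed gives
    identical output bytes).  Fragments shorter than the read length are
    handled by read-through truncation (both mates cover the whole
    fragment).
    """
    import os

    import pyfaidx

    rng = np.random.default_rng(cfg.seed)
    fa = pyfaidx.Fasta(cfg.reference)
    panel = pd.read_csv(
        cfg.panel, sep="\t", header=None, usecols=[0, 1, 2],
        names=["contig", "start", "end"], dtype={"contig": str},
    )
    contig_arrays = {
        name: np.frombuffer(str(fa[name][:]).upper().encode(), dtype=np.uint8)
        for name in fa.keys()
    }

    dist = parse_count_dist(cfg.per_strand_reads)
    n = cfg.n_molecules
    plus_counts, minus_counts = dist.sample(rng, n)

    interval_lens = (panel["end"] - panel["start"]).to_numpy()
    interval_idx = rng.choice(len(panel), size=n, p=interval_lens / interval_lens.sum())
    frag_lens = np.clip(
        np.rint(rng.normal(cfg.fragment_mean, cfg.fragment_sd, size=n)).astype(int),
        cfg.fragment_min,
        None,
    )

    umis = rng.integers(0, 4, size=(n, 2 * cfg.umi_len))
    lesion_draw = rng.random(n) < cfg.oxidation_rate

    truth_rows = []
    bam_records = []
    fastq_r1, fastq_r2 = [], []
    header = make_header(cfg.reference) if write_bam else None
    n_reads = 0

    for m in range(n):
        row = panel.iloc[interval_idx[m]]
        contig = row["contig"]
        lo, hi = int(row["start"]), int(row["end"])
        flen = int(min(frag_lens[m], hi - lo))
        start = int(rng.integers(lo, hi - flen + 1))
        end = start + flen
        frag = contig_arrays[contig][start:end]
        u1 = _CODE_TO_BASE[umis[m, : cfg.umi_len]].tobytes().decode()
        u2 = _CODE_TO_BASE[umis[m, cfg.umi_len:]].tobytes().decode()

        # oxidative lesion: one G site on the plus strand reads as T
        lesion_pos = -1
        plus_template = frag
        if lesion_draw[m]:
            g_sites = np.nonzero(frag == ord("G"))[0]
            if g_sites.size:
                lesion_pos = int(g_sites[rng.integers(0, g_sites.size)])
                plus_template = frag.copy()
                plus_template[lesion_pos] = ord("T")

        rl = min(cfg.read_length, flen)
        error_log = []
        for strand, count, template, barcode in (
            ("plus", int(plus_counts[m]), plus_template, u1 + u2),
            ("minus", int(minus_counts[m]), frag, u2 + u1),
        ):
            for rep in range(count):
                qname = f"M{m:06d}:{strand}:{rep}"
                reads = _emit_read_pair(
                    rng, cfg, strand, rep, start, end, rl, template, error_log
                )
                if write_bam:
                    bam_records.extend(
                        _pair_to_bam(header, qname, barcode, contig, start, end, rl, reads)
                    )
                if write_fastq:
                    fq1, fq2 = _pair_to_fastq(cfg, qname, u1, u2, strand, reads)
                    fastq_r1.append(fq1)
                    fastq_r2.append(fq2)
                n_reads += 1

        truth_rows.append(
            {
                "molecule_id": m,
                "contig": contig,
                "start": start,
                "end": end,
                "umi_plus": u1 + u2,
                "n_plus": int(plus_counts[m]),
                "n_minus": int(minus_counts[m]),
                "lesion_offset": lesion_pos,
                "true_seq": frag.tobytes().decode(),
                "errors": json.dumps(error_log),
            }
        )

    # design-noncompliant pairs: spacer base mutated, FASTQ only
    for j in range(cfg.n_spacer_fail):
        row = panel.iloc[int(rng.integers(0, len(panel)))]
        contig = row["contig"]
        lo, hi = int(row["start"]), int(row["end"])
        rl = cfg.read_length
        start = int(rng.integers(lo, hi - 2 * rl))
        seg = contig_arrays[contig][start: start + rl].tobytes().decode()
        qual = chr(cfg.quality_high + 33) * (rl + cfg.umi_len + 1)
        umi = _CODE_TO_BASE[rng.integers(0, 4, size=cfg.umi_len)].tobytes().decode()
        bad_spacer = "ACG"[int(rng.integers(0, 3))]  # anything but T
        fastq_r1.append((f"BAD{j:05d}", umi + bad_spacer + seg, qual))
        fastq_r2.append((f"BAD{j:05d}", umi + "T" + seg, qual))

    os.makedirs(out_dir, exist_ok=True)
    bam_path = r1_path = r2_path = None
    if write_bam:
        bam_path = os.path.join(out_dir, "simulated.bam")
        write_records_bam(bam_path, bam_records, header)
    if write_fastq:
        r1_path = os.path.join(out_dir, "simulated_R1.fastq")
        r2_path = os.path.join(out_dir, "simulated_R2.fastq")
        for path, entries in ((r1_path, fastq_r1), (r2_path, fastq_r2)):
            with open(path, "w") as fh:
                for name, seq, qual in entries:
                    fh.write(f"@{name}\n{seq}\n+\n{qual}\n")

    truth = pd.DataFrame(truth_rows)
    truth_path = os.path.join(out_dir, "truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimResult(
        bam=bam_path,
        fastq_r1=r1_path,
        fastq_r2=r2_path,
        truth_path=truth_path,
        truth=truth,
        config=cfg,
        n_reads=n_reads,
    )


def _emit_read_pair(rng, cfg, strand, rep, start, end, rl, template, error_log):
    """Draw one read pair of one strand replicate, with independent errors.

    Returns [(ref_start, is_reverse, seq, qual), ...] for R1 then R2, in
    reference orientation.  R1 covers the fragment end carrying this
    strand's 5' adapter.
    """
    if strand == "plus":
        layout = ((start, False), (end - rl, True))
    else:
        layout = ((end - rl, True), (start, False))

    reads = []
    for mate, (rstart, rev) in enumerate(layout, start=1):
        off = rstart - start
        seq = template[off: off + rl].copy()
        n_err = rng.binomial(rl, cfg.seq_error_rate) if cfg.seq_error_rate > 0 else 0
        if n_err:
            pos = rng.choice(rl, size=n_err, replace=False)
            for p in pos:
                code = np.nonzero(_CODE_TO_BASE == seq[p])[0][0]
                new = _CODE_TO_BASE[(code + 1 + rng.integers(0, 3)) % 4]
                seq[p] = new
                error_log.append(
                    {
                        "strand": strand,
                        "rep": rep,
                        "mate": mate,
                        "ref_pos": int(rstart + p),
                        "base": chr(new),
                    }
                )
        qual = np.where(
            rng.random(rl) < cfg.frac_below_q30, cfg.quality_low, cfg.quality_high
        ).astype(np.uint8)
        reads.append((rstart, rev, seq, qual))
    return reads


def _pair_to_bam(header, qname, barcode, contig, start, end, rl, reads):
    tagged = f"{qname}{BARCODE_DELIM}{barcode}"
    (p1, rev1, s1, q1), (p2, rev2, s2, q2) = reads
    flen = end - start
    tlen = -flen if rev1 else flen
    return [
        _segment(header, tagged, contig, p1 + 1, f"{rl}M", rev1, rev2,
                 s1.tobytes().decode(), q1, True, contig, p2 + 1, tlen),
        _segment(header, tagged, contig, p2 + 1, f"{rl}M", rev2, rev1,
                 s2.tobytes().decode(), q2, False, contig, p1 + 1, -tlen),
    ]


def _pair_to_fastq(cfg, qname, u1, u2, strand, reads):
    """FASTQ entries in physical read orientation, UMI+spacer prepended."""
    umi_r1, umi_r2 = (u1, u2) if strand == "plus" else (u2, u1)
    out = []
    for umi, (_, rev, seq, qual) in zip((umi_r1, umi_r2), reads):
        if rev:
            seq = np.array([_COMPLEMENT[b] for b in seq[::-1]], dtype=np.uint8)
            qual = qual[::-1]
        full_seq = umi + cfg.spacer + seq.tobytes().decode()
        full_qual = chr(cfg.quality_high + 33) * (len(umi) + 1) + "".join(
            chr(q + 33) for q in qual
        )
        out.append((qname, full_seq, full_qual))
    return out


# ---------------------------------------------------------------------------
# analytic expectations

#: value of each output stream (per molecule) for strand pattern (a, b),
#: a/b in {0, 1, 2+} read-count classes
_STREAM_VALUE = {
    "sscs": lambda a, b: (a == 2) + (b == 2),
    "sc_by_sscs": lambda a, b: int((a == 1 and b == 2) or (a == 2 and b == 1)),
    "sc_by_singleton_pairs": lambda a, b: int(a == 1 and b == 1),
    "uncorrected_singletons": lambda a, b: int((a == 1 and b == 0) or (a == 0 and b == 1)),
    "dcs_traditional": lambda a, b: int(a == 2 and b == 2),
    "dcs_with_sc": lambda a, b: int(a >= 1 and b >= 1),
}


def expected_stream_sizes(dist: str | CountDistribution, n_molecules: int) -> dict:
    """Closed-form expected pipeline stream counts (mean and sd).

    Derived from the per-strand read-count distribution: pattern
    (>=2, >=2) forms a DCS in both modes; (>=2, 1) and (1, 1) form a DCS
    only with Singleton Correction; (>=2, 0) stays an unpaired SSCS;
    (1, 0) stays an uncorrected singleton.  Counts are sums of iid
    per-molecule contributions, so means and variances scale with n.
    """
    if isinstance(dist, str):
        dist = parse_count_dist(dist)
    m = dist.pattern_probs()
    out = {}
    for name, value in _STREAM_VALUE.items():
        ex = ex2 = 0.0
        for a in range(3):
            for b in range(3):
                v = value(a, b)
                ex += m[a, b] * v
                ex2 += m[a, b] * v * v
        var = ex2 - ex * ex
        out[name] = {
            "mean": n_molecules * ex,
            "sd": math.sqrt(max(n_molecules * var, 0.0)),
        }
    return out
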