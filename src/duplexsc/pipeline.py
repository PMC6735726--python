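"""End-to-end consensus pipeline: group -> collapse -> correct -> duplex -> merge.

Consumes a coordinate-sorted, barcode-tagged BAM and produces the consensus
BAM streams plus a run manifest with read/stream counts at every stage
boundary.  Singleton Correction can be toggled to compare the traditional
duplex workflow with the extended one.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict, field

from . import bamio
from .duplex import merge_all_unique, pair_strands
from .families import duplex_key, group_pairs
from .metrics import CoverageReport, fragment_coverage
from .sscs import (
    ConsensusConfig,
    collapse_family,
    route_families,
    singleton_pair,
)
from .singleton_correction import run_singleton_correction

__all__ = ["run_pipeline", "PipelineResult"]


@dataclass
class PipelineResult:
    counts: dict
    paths: dict
    coverage_traditional: CoverageReport | None = None
    coverage_sc: CoverageReport | None = None
    streams: dict = field(default_factory=dict)


def run_pipeline(
    bam: str,
    reference: str,
    out_dir: str,
    panel: str | None = None,
    cfg: ConsensusConfig | None = None,
    with_sc: bool = True,
    keep_streams: bool = False,
) -> PipelineResult:
    """Run the full error-suppression pipeline on an aligned, tagged BAM.

    Writes the consensus streams to ``out_dir`` and, when a panel is given,
    computes fragment-coverage based efficiency and recovery for both the
    traditional and (if enabled) the Singleton Correction workflow.
    """
    cfg = cfg or ConsensusConfig()
    os.makedirs(out_dir, exist_ok=True)

    pairs, filter_stats = bamio.read_pairs(bam)
    families = group_pairs(pairs)
    collapsible, singleton_fams = route_families(families)
    sscs_list = [collapse_family(f, cfg) for f in collapsible]
    singletons = [singleton_pair(f) for f in singleton_fams]

    counts = {
        "filter": filter_stats,
        "pairs_kept": len(pairs),
        "families": len(families),
        "sscs": len(sscs_list),
        "singletons": len(singletons),
        "with_sc": with_sc,
        "config": asdict(cfg),
    }
    assert sum(f.size for f in families) == len(pairs)

    paths = {}

    def _write(name, stream):
        paths[name] = bamio.write_consensus_bam(
            os.path.join(out_dir, name + ".bam"), stream, reference
        )

    _write("sscs", sscs_list)
    _write("singletons", singletons)

    from collections import Counter

    hist = Counter(f.size for f in families)
    hist_path = os.path.join(out_dir, "family_sizes.tsv")
    with open(hist_path, "w") as fh:
        fh.write("family_size\tcount\n")
        for size in sorted(hist):
            fh.write(f"{size}\t{hist[size]}\n")
    paths["family_sizes"] = hist_path

    # traditional duplex workflow
    dcs_trad, unpaired_trad = pair_strands(sscs_list)
    _write("dcs", dcs_trad)
    counts["dcs_traditional"] = len(dcs_trad)
    counts["unpaired_sscs_traditional"] = len(unpaired_trad)

    streams = {
        "sscs": sscs_list,
        "singletons": singletons,
        "dcs_traditional": dcs_trad,
    }

    if with_sc:
        sc = run_singleton_correction(singletons, sscs_list, cfg)
        counts["sc_by_sscs"] = len(sc.by_sscs)
        counts["sc_by_singleton"] = len(sc.by_singleton)
        counts["uncorrected_singletons"] = len(sc.uncorrected)
        assert (
            len(sc.by_sscs) + len(sc.by_singleton) + len(sc.uncorrected)
            == len(singletons)
        )
        _write("sscs.singleton.sscs_corrected", sc.by_sscs)
        _write("sscs.singleton.singleton_corrected", sc.by_singleton)
        _write("uncorrected_singletons", sc.uncorrected)

        merged_sc = sscs_list + sc.corrected
        _write("sscs_sc", merged_sc)
        dcs_sc, unpaired_sc = pair_strands(merged_sc)
        # corrected singletons always find their partner in the merged stream
        assert all(c.provenance == "SSCS" for c in unpaired_sc)
        _write("dcs_sc", dcs_sc)
        counts["dcs_sc"] = len(dcs_sc)
        counts["unpaired_sscs_sc"] = len(unpaired_sc)
        all_unique = merge_all_unique(dcs_sc, unpaired_sc, sc.uncorrected)
        streams.update(
            {
                "sc_by_sscs": sc.by_sscs,
                "sc_by_singleton": sc.by_singleton,
                "uncorrected_singletons": sc.uncorrected,
                "sscs_sc": merged_sc,
                "dcs_sc": dcs_sc,
            }
        )
    else:
        # without correction, a molecule may be represented both by a strand
        # consensus and by singletons of the other strand (or by two
        # complementary singletons); the merged file keeps one representative
        # per molecule, preferring the consensus
        covered = {duplex_key(s.key) for s in sscs_list}
        lone = []
        for s in singletons:
            dk = duplex_key(s.key)
            if dk not in covered:
                covered.add(dk)
                lone.append(s)
        all_unique = merge_all_unique(dcs_trad, unpaired_trad, lone)

    _write("all_unique_molecules", all_unique)
    counts["all_unique_molecules"] = len(all_unique)
    if counts["singletons"]:
        counts["sc_rate"] = (
            (counts.get("sc_by_sscs", 0) + counts.get("sc_by_singleton", 0))
            / counts["singletons"]
        )
    counts["singleton_fraction"] = (
        counts["singletons"] / counts["families"] if counts["families"] else 0.0
    )

    cov_trad = cov_sc = None
    if panel is not None:
        cov_unc = fragment_coverage(bam, panel)
        cov_trad = CoverageReport(
            cov_uncollapsed=cov_unc,
            cov_sscs=fragment_coverage(paths["sscs"], panel),
            cov_dcs=fragment_coverage(paths["dcs"], panel),
        )
        counts["coverage_traditional"] = asdict(cov_trad)
        if with_sc:
            cov_sc = CoverageReport(
                cov_uncollapsed=cov_unc,
                cov_sscs=fragment_coverage(paths["sscs_sc"], panel),
                cov_dcs=fragment_coverage(paths["dcs_sc"], panel),
            )
            counts["coverage_sc"] = asdict(cov_sc)

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump({"input": os.path.basename(bam), "counts": counts}, fh, indent=2)
    paths["manifest"] = os.path.join(out_dir, "manifest.json")

    return PipelineResult(
        counts=counts,
        paths=paths,
        coverage_traditional=cov_trad,
        coverage_sc=cov_sc,
        streams=streams if keep_streams else {},
    )
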