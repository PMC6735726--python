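"""In-silico downsampling of paired reads and depth sweeps.

Sampling operates on templates (query names), never on single records, so
mates stay together.  Coverage targeting estimates the keep fraction from
fragment coverage and applies an independent Bernoulli draw per template;
given the same input and seed the output is byte-identical.
"""

from __future__ import annotations

import os
import tempfile

import numpy as np
import pandas as pd
import pysam

from .metrics import fragment_coverage
from .pipeline import run_pipeline
from .sscs import ConsensusConfig

__all__ = ["downsample_bam", "depth_sweep"]


def downsample_bam(
    in_bam: str,
    out_bam: str,
    target_cov: float | None = None,
    fraction: float | None = None,
    panel: str | None = None,
    seed: int = 0,
) -> dict:
    """Thin a coordinate-sorted BAM to a target fragment coverage.

    Exactly one of ``target_cov`` (requires ``panel``) or ``fraction`` must
    be given.  Returns the keep fraction and template counts.
    """
    if (target_cov is None) == (fraction is None):
        raise ValueError("specify exactly one of target_cov or fraction")
    if target_cov is not None:
        if panel is None:
            raise ValueError("target_cov requires a panel BED")
        current = fragment_coverage(in_bam, panel)
        if target_cov > current:
            raise ValueError(
                f"target coverage {target_cov} exceeds current coverage {current:.1f}"
            )
        fraction = target_cov / current

    rng = np.random.default_rng(seed)
    decisions: dict[str, bool] = {}
    kept = 0
    with pysam.AlignmentFile(in_bam, "rb") as src:
        with pysam.AlignmentFile(out_bam, "wb", header=src.header) as dst:
            for rec in src.fetch(until_eof=True):
                keep = decisions.get(rec.query_name)
                if keep is None:
                    keep = fraction >= 1.0 or rng.random() < fraction
                    decisions[rec.query_name] = keep
                    kept += keep
                if keep:
                    dst.write(rec)
    pysam.index(out_bam)
    return {
        "fraction": fraction,
        "templates_in": len(decisions),
        "templates_kept": kept,
    }


def depth_sweep(
    bam: str,
    reference: str,
    panel: str,
    targets: list[float],
    repeats: int = 10,
    seed: int = 0,
    cfg: ConsensusConfig | None = None,
) -> pd.DataFrame:
    """Run the full pipeline over a grid of downsampled depths.

    ``targets`` are fragment-coverage targets, conventionally sorted
    descending.  Each (target, repeat) cell downsamples with its own
    derived seed and records coverage, efficiency, recovery, singleton
    fraction and Singleton Correction rate for both workflows.
    """
    rows = []
    current = fragment_coverage(bam, panel)
    for ti, target in enumerate(targets):
        for rep in range(repeats):
            cell_seed = (seed * 1000003 + ti * 1009 + rep) % (2**31)
            with tempfile.TemporaryDirectory() as tmp:
                ds_bam = os.path.join(tmp, "ds.bam")
                info = downsample_bam(
                    bam, ds_bam, target_cov=min(target, current), panel=panel,
                    seed=cell_seed,
                )
                res = run_pipeline(
                    ds_bam, reference, os.path.join(tmp, "run"), panel=panel,
                    cfg=cfg, with_sc=True,
                )
            cov_t, cov_s = res.coverage_traditional, res.coverage_sc
            rows.append(
                {
                    "target_cov": target,
                    "repeat": rep,
                    "seed": cell_seed,
                    "keep_fraction": info["fraction"],
                    "cov_uncollapsed": cov_t.cov_uncollapsed,
                    "cov_sscs": cov_t.cov_sscs,
                    "cov_dcs": cov_t.cov_dcs,
                    "cov_sscs_sc": cov_s.cov_sscs,
                    "cov_dcs_sc": cov_s.cov_dcs,
                    "efficiency_sscs": cov_t.efficiency_sscs,
                    "efficiency_dcs": cov_t.efficiency_dcs,
                    "efficiency_sscs_sc": cov_s.efficiency_sscs,
                    "efficiency_dcs_sc": cov_s.efficiency_dcs,
                    "recovery_dcs": cov_t.recovery_dcs,
                    "recovery_dcs_sc": cov_s.recovery_dcs,
                    "families": res.counts["families"],
                    "singletons": res.counts["singletons"],
                    "singleton_fraction": res.counts["singleton_fraction"],
                    "sc_rate": res.counts.get("sc_rate"),
                }
            )
    return pd.DataFrame(rows)
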