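"""Shared pipeline-driver helpers for end-to-end tests."""

from dataclasses import dataclass

import pandas as pd
import pytest

from pyrgedna.align import align_identity
from pyrgedna.asvtable import AsvTable
from pyrgedna.cli import _qc_and_merge_pair_files
from pyrgedna.config import PipelineConfig
from pyrgedna.curation import curate
from pyrgedna.detection import call_sites
from pyrgedna.reads import dereplicate
from pyrgedna.simulate import (
    simulate_landscape,
    simulate_reference_panel,
    simulate_sample_reads,
)


@dataclass
class PipelineResult:
    panel: object
    sites: pd.DataFrame
    occupancy: dict
    truth: object
    input_table: AsvTable
    curated: AsvTable
    log: pd.DataFrame
    sample_calls: pd.DataFrame
    site_calls: list


def run_simulated_pipeline(cfg: PipelineConfig, seed: int) -> PipelineResult:
    """Simulate reads, run QC/merge/derep, curate, and call sites."""
    align_identity.cache_clear()  # bound memory across repeated landscapes
    panel, lineage_region = simulate_reference_panel(cfg.sim, seed)
    sites, occupancy = simulate_landscape(
        cfg.sim, panel, lineage_region, seed + 1
    )
    fastq, truth = simulate_sample_reads(
        cfg.sim, panel, sites, occupancy, seed + 2
    )
    merged_by_sample = {}
    for sample, (r1, r2) in fastq.items():
        merged, _ = _qc_and_merge_pair_files(r1, r2, cfg)
        merged_by_sample[sample] = merged
    samples_df = pd.DataFrame(
        {
            "sample": list(fastq),
            "site": [s.rsplit("_S", 1)[0] for s in fastq],
        }
    )
    samples_df["batch"] = [
        str(sites.loc[site, "batch"]) for site in samples_df["site"]
    ]
    samples_df = samples_df.set_index("sample")
    table = dereplicate(merged_by_sample, samples=samples_df)
    curated, log = curate(table, panel, sites, cfg.curation)
    sample_calls, site_calls = call_sites(curated, sites)
    return PipelineResult(
        panel=panel,
        sites=sites,
        occupancy=occupancy,
        truth=truth,
        input_table=table,
        curated=curated,
        log=log,
        sample_calls=sample_calls,
        site_calls=site_calls,
    )
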