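from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from tilescan import fdr, normalize, regions, scan, synthetic
from tilescan import cnv as cnv_mod

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

PIPELINE_SEED = 1


@pytest.fixture(scope="session")
def default_plan():
    return synthetic.default_plan(seed=PIPELINE_SEED)


@pytest.fixture(scope="session")
def default_truth(default_plan):
    truth = synthetic.default_truth(default_plan)
    truth.validate_against(default_plan)
    return truth


@pytest.fixture(scope="session")
def default_probes(default_plan):
    return synthetic.build_probe_set(default_plan)


@pytest.fixture(scope="session")
def scan_config(default_plan):
    hd = tuple((c, s, e) for c, s, e, _ in default_plan.high_density_regions)
    return scan.ScanConfig(high_density_regions=hd)


@pytest.fixture(scope="session")
def pipeline_run(default_plan, default_truth, default_probes, scan_config):
    """Full default pipeline on the 1000x-scaled genome: simulate,
    normalize, scan, FDR, SFs, SDRs, CNV calls.  Shared across the suite."""
    matrix = synthetic.simulate_intensities(
        default_probes, default_truth, synthetic.NoiseModel(),
        n_per_group=7, seed=PIPELINE_SEED,
    )
    norm = normalize.log_transform(normalize.quantile_normalize(matrix))
    result = scan.scan_genome(norm, default_probes, scan_config)
    fr = fdr.fdr_analysis(
        result["p_value"].where(result["tested"]).to_numpy(), target_fdr=0.001
    )
    sfs = regions.call_sfs(result, fr)
    sdrs = regions.merge_sdrs(sfs, segments=default_plan.segments_frame())
    calls = cnv_mod.call_cnv(sdrs, sfs)
    return {
        "plan": default_plan,
        "truth": default_truth,
        "probes": default_probes,
        "matrix": matrix,
        "norm": norm,
        "scan": result,
        "fdr": fr,
        "sfs": sfs,
        "sdrs": sdrs,
        "cnv": calls,
    }


@pytest.fixture()
def tiny_annotation():
    """Two genes on one chromosome, opposite strands, two exons each."""
    import pandas as pd

    from tilescan.io import GeneAnnotation

    genes = pd.DataFrame(
        [
            ("g1", "c", 1000, 2000, "+"),
            ("g2", "c", 5000, 6000, "-"),
        ],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
    exons = pd.DataFrame(
        [
            ("g1", "c", 1000, 1300),
            ("g1", "c", 1700, 2000),
            ("g2", "c", 5000, 5400),
            ("g2", "c", 5600, 6000),
        ],
        columns=["gene_id", "chrom", "start", "end"],
    )
    return GeneAnnotation(genes=genes, exons=exons)
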