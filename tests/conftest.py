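import dataclasses

import pytest

from coexnet.network import NetworkConfig
from coexnet.pipeline import PipelineConfig, run_pipeline
from coexnet.preprocess import PreprocessConfig
from coexnet.synthdata import SyntheticDesign, generate_dataset

#: replicate seeds used for the multi-seed recovery and diagnosis checks
SEEDS = (11, 12, 13, 14, 15)


def run_default_pipeline(ds, beta=8, run_permutations=False, n_perm=200, seed=3):
    """Full pipeline under the study conditions; the generator output is
    already on a log2-like scale, so no further transform is applied."""
    cfg = PipelineConfig(
        preprocess=PreprocessConfig(transform="none"),
        network=NetworkConfig(beta=beta),
        run_permutations=run_permutations,
        n_perm=n_perm,
        seed=seed,
    )
    return run_pipeline(
        ds.expression,
        ds.detection,
        ds.traits,
        ds.probe_records,
        ds.snp_catalog,
        ds.probe_records["eqtl_status"],
        cfg,
    )


@pytest.fixture(scope="session")
def default_dataset():
    return generate_dataset(SyntheticDesign())


@pytest.fixture(scope="session")
def five_seed_runs():
    """(dataset, pipeline result) for the default design across 5 seeds."""
    out = {}
    for seed in SEEDS:
        ds = generate_dataset(dataclasses.replace(SyntheticDesign(), seed=seed))
        out[seed] = (ds, run_default_pipeline(ds))
    return out


@pytest.fixture(scope="session")
def default_result(five_seed_runs):
    return five_seed_runs[11][1]
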