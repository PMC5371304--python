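"""Shared fixtures: a small synthetic bundle and its pipeline run.

The bundle is deliberately small (hundreds of analytes, thousands of reads)
so the whole suite stays fast; generator statistics are exercised at larger
sizes inside the tests that need them.
"""

import warnings

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from cirrnet.pipeline import PipelineConfig, run_all
from cirrnet.simulate import SimulationConfig, simulate_bundle, write_bundle

SMALL = dict(
    seed=11,
    n_mrna=600,
    n_lncrna=80,
    n_mirna=40,
    reads_per_sample=3000,
    genome_length=2_000_000,
    n_tf=20,
    n_planted_tf_mirna=15,
    n_negative_tf_mirna=8,
    n_planted_mirna_mrna=60,
    n_decoy_mirna_mrna=40,
    n_planted_mirna_lncrna=15,
    n_decoy_mirna_lncrna=10,
    n_ppi=45,
    n_go_terms=25,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(**SMALL)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config)


@pytest.fixture(scope="session")
def bundle_dir(small_bundle, tmp_path_factory):
    bundle, truth = small_bundle
    path = tmp_path_factory.mktemp("bundle")
    write_bundle(bundle, truth, path)
    return path


@pytest.fixture(scope="session")
def pipeline_run(bundle_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("results")
    cfg = PipelineConfig(input_dir=str(bundle_dir), output_dir=str(out))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = run_all(cfg)
    return cfg, manifest
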