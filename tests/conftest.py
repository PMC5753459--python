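"""Shared fixtures: a scaled-down synthetic study generated once per session."""

from __future__ import annotations

import pytest
from hypothesis import settings

from ionsom.pipeline import PipelineConfig, run_pipeline

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")
from ionsom.simulate import SimulationConfig, write_fixture


def small_config(seed: int = 11) -> SimulationConfig:
    """A fast, scaled-down study: 2 patients, 3 tumor samples, 60 somatic."""
    return SimulationConfig(
        seed=seed,
        n_regions=8,
        region_length=2500,
        n_patients=2,
        tumor_samples_per_patient=3,
        n_somatic_per_patient=30,
        tumor_depth_mean=600,
        normal_depth_mean=600,
        n_artifact_loci={"homopolymer_slippage": 20,
                         "strand_bias": 15,
                         "low_af_noise": 20},
        n_germline_per_patient=8,
    )


@pytest.fixture(scope="session")
def sim_config():
    return small_config()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, sim_config):
    d = tmp_path_factory.mktemp("fixture")
    write_fixture(d, sim_config)
    return d


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, fixture_dir, sim_config):
    out = tmp_path_factory.mktemp("pipeline_out")
    cfg = PipelineConfig(fixture_dir=str(fixture_dir), output_dir=str(out),
                         seed=sim_config.seed)
    return run_pipeline(cfg)
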