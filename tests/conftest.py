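import warnings
from pathlib import Path

import numpy as np
import pytest

from itvus import models as builtin
from itvus.pipeline import PipelineConfig, run_pipeline
from itvus.synthfix import simulate_study

STUDY_SEED = 1


@pytest.fixture(scope="session")
def models():
    return builtin.builtin_models()


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """Synthetic study fixture set written to disk, one per session."""
    out = tmp_path_factory.mktemp("study")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_study(seed=STUDY_SEED, out_dir=out)


@pytest.fixture(scope="session")
def study_config(study):
    p = study.paths
    return PipelineConfig(
        reference=str(p["reference"]), vcf=str(p["vcf"]),
        genes=str(p["genes"]), capture_bed=str(p["capture_bed"]),
        af_table=str(p["af_table"]), factor_table=str(p["factors"]))


@pytest.fixture(scope="session")
def pipeline_result(study_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(study_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
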