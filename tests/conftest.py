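import warnings

import numpy as np
import pytest

from lincscreen import (
    PipelineConfig,
    SyntheticConfig,
    generate_annotation,
    generate_counts,
    run_pipeline,
)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def syn_config():
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def annotation(syn_config):
    return generate_annotation(syn_config)


@pytest.fixture(scope="session")
def count_matrices(annotation, syn_config):
    return generate_counts(annotation, syn_config)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(synthetic={}, seed=11, outdir=str(out))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n):
    return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, n)])
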