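"""Shared fixtures: the bundled toy world, its guide design, and haplotypes."""

from __future__ import annotations

import numpy as np
import pytest

from casbreak.config import PipelineConfig
from casbreak.pipeline import design_all
from casbreak.sim_reads import apply_svs_to_reference
from casbreak.toy import make_toy_world


@pytest.fixture(scope="session")
def toy_world():
    return make_toy_world(1234)


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def toy_design(toy_world, pipeline_config):
    result = design_all(
        toy_world.catalog, toy_world.reference, toy_world.element, pipeline_config
    )
    assert not result.skipped
    return result


@pytest.fixture(scope="session")
def toy_haplotypes(toy_world):
    return apply_svs_to_reference(toy_world.reference, toy_world.truth_svs)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
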