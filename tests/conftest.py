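"""Shared fixtures: the four-tone benchmark signal, its selected VMD
penalty, and pipeline runs on the default brain phantom (session-scoped
because voxelwise decomposition is the expensive step)."""

import warnings

import numpy as np
import pytest

from modespec.benchmark import run_benchmark
from modespec.decompose import VMDConfig, select_alpha, vmd_decompose
from modespec.pipeline import PipelineConfig, run_pipeline
from modespec.synthetic import (BrainPhantomConfig, ToneMixtureConfig,
                                make_brain_phantom, make_tone_mixtures)

N_PHANTOM_SEEDS = 10


@pytest.fixture(scope="session")
def tone_mixtures():
    return make_tone_mixtures()


@pytest.fixture(scope="session")
def clean_alpha(tone_mixtures):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return select_alpha(tone_mixtures.clean, K=4)


@pytest.fixture(scope="session")
def clean_vmd(tone_mixtures, clean_alpha):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return vmd_decompose(tone_mixtures.clean,
                             VMDConfig(n_modes=4, alpha=clean_alpha.alpha))


@pytest.fixture(scope="session")
def benchmark_result():
    """All three methods on 50 noisy realizations at the target SNR."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_benchmark(ToneMixtureConfig(seed=0), reduced_reps=50)


@pytest.fixture(scope="session")
def phantom_pipelines():
    """Full pipeline runs on the default phantom across seeds."""
    out = []
    for seed in range(N_PHANTOM_SEEDS):
        cfg = BrainPhantomConfig(seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out.append((cfg, run_pipeline(PipelineConfig(phantom=cfg,
                                                         seed=seed))))
    return out


@pytest.fixture(scope="session")
def default_pipeline(phantom_pipelines):
    return phantom_pipelines[0][1]


@pytest.fixture(scope="session")
def default_phantom():
    return make_brain_phantom(BrainPhantomConfig(seed=0))
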