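import numpy as np
import pytest

from borealshift import pipeline as pl
from borealshift import synthetic as syn
from borealshift.config import PipelineConfig
from borealshift.synthetic import GenerationConfig


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    """The standard desk-scale study conditions (256x256, 2,000 plots)."""
    return PipelineConfig(seed=1)


@pytest.fixture(scope="session")
def default_run(default_config, tmp_path_factory):
    """One full pipeline run under the default study conditions.

    Session-scoped: the end-to-end analyses (forcing, chronosequence,
    conservation, recovery) all interrogate this single run.
    """
    outdir = tmp_path_factory.mktemp("default_run")
    return pl.run_pipeline(default_config, outdir=outdir)


def small_pipeline_config(seed: int = 5) -> PipelineConfig:
    """A fast reduced-size configuration for structural/determinism tests."""
    return PipelineConfig(
        seed=seed,
        generation=GenerationConfig(grid_shape=(64, 64), n_fires=8, blur_sigma=4.0),
        n_plots=500,
        undersample_target=40,
        canopy_n_per_stratum=60,
        albedo_n_per_bin=60,
        albedo_coarse_factor=8,
        n_albedo_days=3,
        cover_grid={
            "n_trees": [40],
            "max_features": ["sqrt"],
            "min_samples_split": [2],
            "min_samples_leaf": [1],
        },
        cv_repeats=1,
        albedo_hyperparams={
            "n_trees": 40,
            "max_features": 1.0,
            "min_samples_split": 5,
            "min_samples_leaf": 2,
        },
    )


@pytest.fixture()
def small_config() -> PipelineConfig:
    return small_pipeline_config()


@pytest.fixture(scope="session")
def small_truth() -> syn.LandscapeTruth:
    """A small synthetic landscape shared by generator-level tests."""
    cfg = GenerationConfig(grid_shape=(64, 64), n_fires=6, blur_sigma=4.0)
    return syn.generate_truth(cfg, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
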