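import numpy as np
import pandas as pd
import pytest

from seaway import synthetic_domain as sd
from seaway.covariates import SampleMatrix, cell_covariates, sample_background
from seaway.pipeline import PipelineConfig, build_stack
from seaway.synthetic_domain import SyntheticDomainConfig, VirtualSpecies


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig(
        domain=SyntheticDomainConfig(
            extent=(120, 40),
            shelf_width_km=20.0,
            latitude_range=(36.0, 54.0),
            spawning_attractor=(110, 35),
            overwintering_attractor=(10, 35),
            seed=7,
        ),
        n_background=500,
        n_hydrophones=15,
        n_tags=20,
        temp_noise_sd=1.5,
    )


@pytest.fixture(scope="session")
def small_domain(small_config):
    return sd.make_domain(small_config.domain)


@pytest.fixture(scope="session")
def small_stack(small_config, small_domain):
    bathy, lat = small_domain
    return build_stack(bathy, lat, small_config, seed=7)


def make_sample_matrix(
    stack,
    species: VirtualSpecies,
    season: str,
    n_presence: int,
    n_background: int,
    seed: int,
) -> SampleMatrix:
    """Presence cells drawn from true suitability + uniform background."""
    cells = sd.sample_presence_cells(species, stack, season, n_presence, seed=seed)
    pres = cell_covariates(stack, season, cells)
    bg = sample_background(stack, season, n_background, seed=seed)
    data = pd.concat([pres, bg], ignore_index=True)
    labels = np.concatenate([np.ones(len(pres), int), np.zeros(len(bg), int)])
    return SampleMatrix(data, labels, season)


@pytest.fixture(scope="session")
def niche_species() -> VirtualSpecies:
    # sharp quadratic temperature niche with optimum at 9 degC
    c = 40.0
    return VirtualSpecies(
        response_coefficients={"temp": (2 * c * 9.0, -c)}, intercept=3.0 - c * 81.0
    )


@pytest.fixture(scope="session")
def niche_samples(small_stack, niche_species) -> SampleMatrix:
    return make_sample_matrix(small_stack, niche_species, "summer", 150, 500, seed=11)


@pytest.fixture(scope="session")
def pipeline_result(small_config):
    from seaway.pipeline import run_pipeline

    return run_pipeline(small_config, seed=3)
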