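import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

from careflow import (
    SimulationConfig,
    generate_registry,
    pearson_correlation,
    run_pipeline,
)
from careflow.synthetic_registry import separated_archetype_spectra


def separated_archetypes() -> list:
    """The package's well-separated practice-style profiles, with the fixture
    contract (pairwise Pearson correlation < 0.5) asserted."""
    arch = separated_archetype_spectra()
    for i in range(3):
        for j in range(i + 1, 3):
            assert pearson_correlation(arch[i], arch[j]) < 0.5
    return arch


def planted_config(n_patients: int = 6000, seed: int = 11, **kwargs) -> SimulationConfig:
    defaults = dict(
        n_zip_areas=60,
        n_centers=30,
        n_patients=n_patients,
        archetype_spectra=separated_archetypes(),
        spectrum_noise=0.002,
        volume_sigma=0.0,
        seed=seed,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def planted_result():
    """Full pipeline run on a 30-center registry with three well-separated
    planted practice archetypes (200 patients/center)."""
    return run_pipeline(config=planted_config(), seed=11)


@pytest.fixture(scope="session")
def small_registry():
    cfg = SimulationConfig(
        n_zip_areas=12, n_centers=6, n_patients=400, seed=5, volume_sigma=0.0
    )
    registry, truth = generate_registry(cfg)
    return registry, truth, cfg


def make_registry(rows) -> pd.DataFrame:
    """Registry table from (patient, day, zip, provider, procedure, death) rows."""
    return pd.DataFrame(
        rows, columns=["patient_id", "day", "zip", "provider_id", "procedure", "death"]
    )
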