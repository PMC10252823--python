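import numpy as np
import pytest

from isoweb.synthetic import (ScenarioConfig, SourceSpec, TaxonSpec,
                              default_scenario, generate_consumers,
                              generate_environment, generate_sources)


@pytest.fixture(scope="session")
def scenario():
    return default_scenario(seed=123)


@pytest.fixture(scope="session")
def sources_df(scenario):
    return generate_sources(scenario)


@pytest.fixture(scope="session")
def consumers_truth(scenario):
    return generate_consumers(scenario)


@pytest.fixture(scope="session")
def env_df(scenario):
    return generate_environment(scenario)


def small_scenario(seed=0, noise_sd=(1.5, 1.0), areas=("A", "B"),
                   n_per_taxon=4, source_sd=0.6):
    """Two-area, one-season miniature study for fast pipeline tests."""
    season = "rainy"
    sources = [
        SourceSpec("C3_plants", {season: -27.0}, source_sd,
                   {season: 1.5}, source_sd),
        SourceSpec("phytoplankton", {season: -21.0}, source_sd,
                   {season: 4.5}, source_sd),
        SourceSpec("seagrass", {season: -9.5}, source_sd,
                   {season: 8.0}, source_sd),
        SourceSpec("epiphytes", {season: -15.0}, source_sd,
                   {season: 11.0}, source_sd),
    ]
    taxa = [TaxonSpec("fish_1", "fish", "piscivore", n_per_taxon),
            TaxonSpec("fish_2", "fish", "omnivore", n_per_taxon),
            TaxonSpec("mollusk_1", "mollusk", "detritivore", n_per_taxon),
            TaxonSpec("crustacean_1", "crustacean", "zoobenthivore",
                      n_per_taxon)]
    diets = {
        ("A", season, "fish"): (0.55, 0.25, 0.10, 0.10),
        ("A", season, "mollusk"): (0.10, 0.10, 0.65, 0.15),
        ("A", season, "crustacean"): (0.20, 0.40, 0.20, 0.20),
        ("B", season, "fish"): (0.10, 0.60, 0.15, 0.15),
        ("B", season, "mollusk"): (0.25, 0.25, 0.25, 0.25),
        ("B", season, "crustacean"): (0.10, 0.20, 0.10, 0.60),
    }
    env_profile = {var: (mean, 1.0) for var, mean in zip(
        ("depth_cm", "temperature_c", "tds_g_l", "conductivity_ms_cm",
         "salinity_ups", "do_mg_l", "ph", "chlorophyll_ug_l"),
        (100.0, 29.0, 20.0, 40.0, 25.0, 3.0, 7.5, 8.0))}
    return ScenarioConfig(
        areas=list(areas), seasons=[season], sources=sources,
        diet_sources=["C3_plants", "phytoplankton", "seagrass",
                      "epiphytes"],
        guilds={"piscivore": 3.0, "zoobenthivore": 2.7, "planktivore": 2.6,
                "omnivore": 2.6, "detritivore": 2.4},
        taxa=taxa,
        true_diets={k: np.asarray(v) for k, v in diets.items()
                    if k[0] in areas},
        noise_sd=noise_sd,
        env_profiles={(a, season): dict(env_profile) for a in areas},
        seed=seed)
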