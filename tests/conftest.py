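import pytest

from aquafoot.synthetic import SyntheticConfig, generate_fields, generate_scene_series, generate_weather


@pytest.fixture(scope="session")
def noise_free_config():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def noise_free_run(noise_free_config):
    """One noise-free synthetic realisation shared across tests."""
    weather = generate_weather(noise_free_config)
    fields = generate_fields(noise_free_config)
    scenes, truth = generate_scene_series(noise_free_config, weather, fields)
    return {
        "config": noise_free_config,
        "weather": weather,
        "fields": fields,
        "scenes": scenes,
        "truth": truth,
    }
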