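import numpy as np
import pandas as pd
import pytest

from seaflood import ScenarioConfig, MeasurementNoise


def spanning_fraction_config(seed: int, noise: bool = True) -> ScenarioConfig:
    """Scenario with denitrified fractions spanning the observed field range
    (0 to ~0.9), assigned in opposite order at the two stations."""
    kwargs = {}
    if not noise:
        kwargs["measurement_noise"] = MeasurementNoise.none()
        kwargs["noise_peak_rate"] = 0.0
    return ScenarioConfig(
        seed=seed,
        true_denit_fraction={"UC": (0.0, 0.53, 0.75, 0.89),
                             "C": (0.89, 0.75, 0.53, 0.0)},
        **kwargs)


@pytest.fixture
def default_scenario():
    from seaflood import generate_scenario
    return generate_scenario(ScenarioConfig(seed=11))


def even_abundances(n_otus: int, n_samples: int, rng: np.random.Generator,
                    alpha: float = 10.0) -> pd.DataFrame:
    """Near-even Dirichlet communities; every OTU present in every sample."""
    ab = rng.dirichlet(np.full(n_otus, alpha), size=n_samples)
    idx = [f"S{i:02d}" for i in range(n_samples)]
    cols = [f"T{i:03d}" for i in range(n_otus)]
    return pd.DataFrame(ab, index=idx, columns=cols)
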