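import numpy as np
import pandas as pd
import pytest

from pathosig.simulate import PlantedSignature, SimulationConfig, simulate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_config():
    """A compact planted experiment: 2 signatures, 5 decoys, ~70 samples."""
    return SimulationConfig(
        group_sizes={"BRER": 20, "BRTN": 20, "control": 10},
        n_human_probes=200,
        signatures=(
            PlantedSignature(
                organism="Alphatestvirus",
                organism_class="virus",
                target_groups=("BRER",),
                effect_log2=2.5,
                case_prevalence_frac=0.8,
            ),
            PlantedSignature(
                organism="Testomonas",
                organism_class="bacterium",
                target_groups=("BRER", "BRTN"),
                effect_log2=2.5,
                case_prevalence_frac=0.6,
            ),
        ),
        probes_per_signature=4,
        n_decoy_organisms=5,
        seed=424242,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture
def noiseless_null_experiment():
    """No signatures, zero noise: normalized signals are exactly zero."""
    config = SimulationConfig(
        group_sizes={"BRER": 4, "control": 3},
        n_human_probes=5,
        noise_sd_log2=0.0,
        n_decoy_organisms=3,
        seed=7,
    )
    return simulate_experiment(config)


@pytest.fixture
def presence_example():
    """Probe A detected in {s1, s2}, probe B in {s2, s3}, group of 4."""
    presence = pd.DataFrame(
        False, index=["A1", "B1"], columns=["s1", "s2", "s3", "s4"]
    )
    presence.loc["A1", ["s1", "s2"]] = True
    presence.loc["B1", ["s2", "s3"]] = True
    organisms = pd.Series({"A1": "orgA", "B1": "orgA"})
    return presence, organisms
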