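import numpy as np
import pandas as pd
import pytest

from cnisig.simulate import (GenomeLayout, PlantedEvent, SimulationConfig,
                             simulate_cohort, simulate_marker_cohort)


@pytest.fixture(scope="session")
def small_layout():
    return GenomeLayout(chromosomes=(("chr1", 500), ("chr2", 500)), spacing=1000)


@pytest.fixture(scope="session")
def marker_cohort():
    """Dose-level cohort with six planted prognostic markers (defaults)."""
    doses, outcome, beta = simulate_marker_cohort(n_samples=500, seed=42)
    return doses, outcome[["time_months", "event"]], beta


@pytest.fixture(scope="session")
def noiseless_cohort(small_layout):
    """Two-chromosome cohort with two clean planted events (tiny noise)."""
    events = (
        PlantedEvent("gA", "chr1", 125, 249, "gain",
                     frequency={"all": 0.5}, beta=0.7),
        PlantedEvent("lB", "chr2", 250, 374, "loss",
                     frequency={"all": 0.4}, beta=0.5),
    )
    cfg = SimulationConfig(n_samples=40, events=events, noise_sd=0.01, seed=7)
    return simulate_cohort(cfg, small_layout) + (cfg,)


def toy_outcome(times, events):
    return pd.DataFrame({"time_months": np.asarray(times, dtype=float),
                         "event": np.asarray(events, dtype=int)})
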