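import numpy as np
import pandas as pd
import pytest

from cypscreen import ExpressionMatrix, TraitTable
from cypscreen.simulate import (
    PlantedCorrelation,
    PlantedVariant,
    SimulationConfig,
    simulate_dataset,
)

MONOS = SimulationConfig().trait_names


@pytest.fixture
def toy_expr() -> ExpressionMatrix:
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [5.0, 5.0, 5.0, 5.0]],
        index=["PgCYP274-1", "PgCYP274-2", "PgCYP100"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def toy_traits() -> TraitTable:
    rng = np.random.default_rng(11)
    df = pd.DataFrame(
        rng.lognormal(0.5, 0.3, size=(4, 9)),
        index=["s1", "s2", "s3", "s4"],
        columns=list(MONOS),
    )
    return TraitTable(df).with_total()


def planted_panel_config() -> SimulationConfig:
    """Configuration of the shared 42-cultivar panel with every kind of
    planted signal.

    Indices 0..11 are expression-correlated; variants sit on 5..10 so their
    genes survive the correlation screen, as in a real panel where only
    correlated genes enter mutation analysis.  One variant effect per trait:
    stacking several shifted carrier groups on the same trait would mask
    each other.
    """
    return SimulationConfig(
        seed=42,
        n_transcripts=240,
        n_genes=230,
        planted_correlated=[PlantedCorrelation(i, "Rg1", 0.7) for i in range(12)],
        planted_variants=[
            PlantedVariant(5 + i, MONOS[i], 12, 2.5) for i in range(6)
        ],
        planted_module=list(range(20, 30)),
        module_loading=0.9,
        n_background_variants=40,
    )


@pytest.fixture(scope="session")
def planted_panel():
    return simulate_dataset(planted_panel_config())
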