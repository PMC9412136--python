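import numpy as np
import pytest

from karstdiv.community_model import PlotSurvey, Subplot, TraitTable


@pytest.fixture
def herb_survey():
    """One herbaceous plot: four 1 m^2 herb subplots, species A with 8
    individuals in total and species B with 4."""
    subs = [
        Subplot(layer="herb", area_m2=1.0, counts={"A": 2, "B": 1}),
        Subplot(layer="herb", area_m2=1.0, counts={"A": 2, "B": 1}),
        Subplot(layer="herb", area_m2=1.0, counts={"A": 2, "B": 1}),
        Subplot(layer="herb", area_m2=1.0, counts={"A": 2, "B": 1}),
    ]
    return PlotSurvey(plot_id="P1", stage="HE", subplots=subs)


@pytest.fixture
def two_layer_survey():
    """A shrub-stage plot where species X occurs in both shrub and herb
    layers (layer densities must be summed, never an error)."""
    return PlotSurvey(
        plot_id="P2",
        stage="SH",
        subplots=[
            Subplot(layer="shrub", area_m2=16.0, counts={"X": 8, "Y": 4}),
            Subplot(layer="herb", area_m2=1.0, counts={"X": 3, "Z": 2}),
        ],
    )


@pytest.fixture
def small_traits():
    """Three species, six traits, all raw values positive and LDMC < 1."""
    return TraitTable(
        species=["A", "B", "C"],
        traits=np.array(
            [
                [0.2, 0.10, 20.0, 0.20, 10.0, 100.0],
                [2.0, 0.30, 40.0, 0.40, 50.0, 250.0],
                [20.0, 0.50, 60.0, 0.60, 90.0, 400.0],
            ]
        ),
    )


def random_community(rng, max_species=50):
    """Random counts, densities and a valid [0, 1] distance matrix."""
    s = rng.integers(2, max_species + 1)
    counts = rng.integers(0, 40, size=s)
    counts[rng.integers(0, s)] += 2  # ensure N >= 2
    dens = counts * rng.uniform(0.1, 5.0)
    raw = rng.uniform(0.0, 1.0, size=(s, s))
    d = (raw + raw.T) / 2
    np.fill_diagonal(d, 0.0)
    return counts, dens, d
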