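import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import gradient_niche as gn

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture()
def tiny_env():
    """Four grassland plots in two regions with simple gradient values."""
    df = pd.DataFrame(
        {
            "region": ["ALB", "ALB", "HAI", "HAI"],
            "habitat": ["grassland"] * 4,
            "LUI": [1.0, 2.0, 3.0, 4.0],
            "pH": [4.0, 5.0, 6.0, 6.5],
        },
        index=pd.Index(["p1", "p2", "p3", "p4"], name="plot_id"),
    )
    return gn.EnvironmentTable(df)


@pytest.fixture()
def tiny_abund(tiny_env):
    counts = pd.DataFrame(
        {"spA": [1, 2, 3, 0], "spB": [0, 4, 0, 4]}, index=tiny_env.plots
    )
    return gn.AbundanceMatrix(counts)


@pytest.fixture()
def tiny_traits():
    df = pd.DataFrame(
        {"shell_size": [2.0, 4.0], "light_pref": [1, 3]},
        index=pd.Index(["spA", "spB"], name="species"),
    )
    return gn.TraitTable(df)


@pytest.fixture()
def tiny_redlist():
    df = pd.DataFrame({"code": ["*", "V"]},
                      index=pd.Index(["spA", "spB"], name="species"))
    return gn.RedListTable(df)


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic study (both habitats, 30 species), shared read-only."""
    return gn.generate_dataset(gn.ScenarioConfig(seed=11))


def random_instance(rng, n_plots=None, n_species=None):
    """A small random environment + abundance pair for oracle comparisons."""
    n_plots = n_plots or int(rng.integers(2, 12))
    n_species = n_species or int(rng.integers(1, 6))
    env = gn.EnvironmentTable(pd.DataFrame({
        "region": ["ALB"] * n_plots,
        "habitat": ["grassland"] * n_plots,
        "LUI": rng.uniform(0.53, 4.52, n_plots),
    }, index=pd.Index([f"p{i}" for i in range(n_plots)], name="plot_id")))
    counts = rng.integers(0, 8, size=(n_plots, n_species))
    # guarantee every species occurs somewhere
    for j in range(n_species):
        if counts[:, j].sum() == 0:
            counts[int(rng.integers(0, n_plots)), j] = 1
    abund = gn.AbundanceMatrix(pd.DataFrame(
        counts, index=env.plots,
        columns=[f"s{j}" for j in range(n_species)]))
    return env, abund
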