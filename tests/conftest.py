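"""Shared fixtures: tiny deterministic networks, panels and studies."""

import numpy as np
import pandas as pd
import pytest

import ozexpo as oz


@pytest.fixture
def tri_network():
    """Three monitors on a small asymmetric triangle."""
    return oz.MonitorNetwork(
        ids=("M01", "M02", "M03"),
        coordinates=np.array([[0.0, 0.0], [4.0, 0.0], [1.0, 3.0]]))


@pytest.fixture
def tri_day():
    return pd.Series({"M01": 30.0, "M02": 50.0, "M03": 40.0})


@pytest.fixture(scope="session")
def small_study():
    """A compact but full simulated study reused across tests."""
    cfg = oz.SimulationConfig(n_monitors=8, n_days=20, n_subjects=60, seed=11)
    return oz.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_panel(small_study):
    return oz.build_daily_panel(small_study.hourly)


def constant_panel(network, n_days=5, value=40.0):
    dates = pd.date_range("2009-01-01", periods=n_days, freq="D")
    return pd.DataFrame(value, index=dates, columns=list(network.ids))
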