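import numpy as np
import pytest

import evacflow as ef


@pytest.fixture(scope="session")
def default_run():
    """One processed default scenario shared by the recovery tests.

    Returns (scenario, panel, anomaly, oriented EOF result, role labels
    aligned with the anomaly grid index).
    """
    scenario = ef.default_scenario(seed=1)
    panel, truth = ef.simulate_panel(scenario)
    valid, report = ef.filter_valid_grids(panel)
    filled = ef.fill_gaps(valid)
    anom = ef.compute_anomaly(filled)
    result = ef.orient_signs(ef.eof_decompose(anom, k=3))
    roles = truth.roles()
    labels = np.array([roles[str(g)] for g in anom.grid_index], dtype=object)
    return {
        "scenario": scenario,
        "panel": filled,
        "report": report,
        "anomaly": anom,
        "eof": result,
        "labels": labels,
    }


@pytest.fixture
def noiseless_run():
    """Default scenario geometry with noise and missingness switched off."""
    scenario = ef.default_scenario(seed=0, noise_dispersion=0.0, missing_rate=0.0)
    panel, truth = ef.simulate_panel(scenario)
    return scenario, panel, truth


def make_panel(pre, post, zones=None):
    """Build a small GridPanel from (G, 24) arrays."""
    pre = np.asarray(pre, dtype=float)
    g = pre.shape[0]
    return ef.GridPanel(
        grid_ids=np.array([f"g{i:03d}" for i in range(g)], dtype=object),
        lon=np.linspace(103.0, 103.1, g),
        lat=np.linspace(33.0, 33.1, g),
        zone=np.array(zones if zones is not None else ["VII"] * g, dtype=object),
        pre=pre,
        post=np.asarray(post, dtype=float),
    )
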