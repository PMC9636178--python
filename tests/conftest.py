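"""Shared fixtures: small synthetic sessions with ground truth."""

import numpy as np
import pytest

from placecode.simulate import SimConfig, generate_session, generate_axon_session
from placecode import behavior as bhv


@pytest.fixture(scope="session")
def small_session():
    """Default-conditions session at a modest cell count, with behavior
    labels already computed."""
    session, truth = generate_session(SimConfig(n_cells=40), seed=7)
    lap_table = bhv.segment_laps(session)
    zone = bhv.anticipation_zone(session, lap_table)
    stop = bhv.detect_lick_stop_lap(session, lap_table, zone)
    bhv.classify_engagement_approach(lap_table)
    return {"session": session, "truth": truth, "lap_table": lap_table,
            "zone": zone, "lick_stop": stop}


@pytest.fixture(scope="session")
def axon_session():
    session, truth = generate_axon_session(seed=5)
    lap_table = bhv.segment_laps(session)
    zone = bhv.anticipation_zone(session, lap_table)
    bhv.detect_lick_stop_lap(session, lap_table, zone)
    return {"session": session, "truth": truth, "lap_table": lap_table}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
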