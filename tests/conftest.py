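import logging

import numpy as np
import pytest

import beeforage as bf

logging.getLogger("beeforage").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def study():
    """One simulated field season under default study conditions."""
    return bf.simulate_study(bf.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def study_tables(study):
    """Derived tables for the shared study: bouts, activity, efficiency, merged."""
    bouts = bf.extract_bouts(bf.clean_events(study.events))
    activity = bf.summarize_activity(bouts, study.bees)
    efficiency = bf.compute_efficiency(study.observations, bouts)
    merged = bf.build_analysis_table(study.bees, study.scores, activity, efficiency)
    return {"bouts": bouts, "activity": activity, "efficiency": efficiency,
            "merged": merged}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def oracle_pair(events, min_duration=2.0):
    """Brute-force restatement of the bout-pairing rule, per bee in time
    order: an 'in' closes the most recent unclosed 'out'; later 'out's of
    a run supersede earlier ones; candidates shorter than min_duration
    are dropped.  Kept independent of the library implementation."""
    bouts = []
    for bee in sorted({e.bee_id for e in events}):
        stream = sorted({e for e in events if e.bee_id == bee},
                        key=lambda e: (e.timestamp, e.direction))
        last_out = None
        for e in stream:
            if e.direction == "out":
                last_out = e.timestamp
            elif last_out is not None:
                if (e.timestamp - last_out).total_seconds() / 60.0 >= min_duration:
                    bouts.append((bee, last_out, e.timestamp))
                last_out = None
    return bouts
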