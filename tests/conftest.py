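import numpy as np
import pandas as pd
import pytest

from birdindex.synthetic import ChecklistTable, StopTable


def make_meta(n, **overrides):
    """Hand-built checklist metadata, all rows passing the standard filters."""
    base = {
        "checklist_id": [f"C{i}" for i in range(n)],
        "location_id": ["L1"] * n,
        "town": ["T01"] * n,
        "observer_id": ["obs1"] * n,
        "date": ["2010-06-01"] * n,
        "year": [2010] * n,
        "start_time": [0.3] * n,
        "protocol": ["traveling"] * n,
        "distance_km": [1.0] * n,
        "duration_hours": [1.0] * n,
        "party_size": [1] * n,
        "complete": [True] * n,
        "group_id": [pd.NA] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


def make_obs(mapping):
    """Species rows from {checklist_id: [species ids]} (count 1 each)."""
    rows = [
        {"checklist_id": cid, "species_id": sp, "count": 1}
        for cid, sps in mapping.items()
        for sp in sps
    ]
    return pd.DataFrame(rows)


def fill_species(k, prefix="F"):
    return [f"{prefix}{j}" for j in range(k)]


@pytest.fixture
def toy_checklists():
    """Six checklists, each with >= 5 species, one with a 6-hour duration."""
    meta = make_meta(6)
    meta.loc[3, "duration_hours"] = 6.0
    obs = make_obs({f"C{i}": fill_species(5) + ["SPX"] * (i == 0) for i in range(6)})
    return ChecklistTable(meta, obs)


@pytest.fixture
def toy_stops():
    runs = pd.DataFrame(
        {
            "route_id": ["R1", "R1"],
            "run_id": ["R1-2010", "R1-2011"],
            "year": [2010, 2011],
            "town": ["T01", "T01"],
            "observer_id": ["bbs1", "bbs1"],
            "quality": ["good", "good"],
        }
    )
    counts = pd.DataFrame(
        {
            "run_id": ["R1-2010", "R1-2010"],
            "stop": [1, 3],
            "species_id": ["A", "A"],
            "count": [2, 1],
        }
    )
    return StopTable(runs, counts, stops_per_route=3)
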