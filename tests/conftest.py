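import pandas as pd
import pytest

from matesite import simulate as sim


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured synthetic monitoring dataset."""
    cfg = sim.SimConfig(
        n_females=12,
        n_males=8,
        n_years=15,
        start_year=2000,
        tag_first_year=2001,
        tag_last_year=2008,
        p_acoustic_tag=1.0,
    )
    registry, detections, sightings, temperature, truth = sim.simulate(cfg, 7)
    return {
        "config": cfg,
        "registry": registry,
        "detections": detections,
        "sightings": sightings,
        "temperature": temperature,
        "truth": truth,
    }


@pytest.fixture
def tiny_registry():
    return pd.DataFrame(
        {
            "shark_id": ["F001", "F002", "M001"],
            "sex": ["F", "F", "M"],
            "tagging_date": pd.to_datetime(["2004-06-15", "2005-06-20", "2004-06-10"]),
            "tag_types": ["PIT+acoustic+roto", "PIT+roto", "PIT+acoustic+roto"],
            "total_length_cm": [250.0, 245.0, 240.0],
            "acoustic_tag_end": pd.to_datetime(["2014-06-12", pd.NaT, "2014-06-07"]),
        }
    )
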