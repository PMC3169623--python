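import numpy as np
import pandas as pd
import pytest

from oceanbeta import OtuTable, SampleMetadata
from oceanbeta.synthetic_data import SimulationParams, generate_community

SMALL_GROUP_SIZES = {
    ("pelagic", "coastal"): 8,
    ("pelagic", "surface_open_ocean"): 8,
    ("pelagic", "deep_open_ocean"): 8,
    ("pelagic", "vent"): 4,
    ("pelagic", "anoxic"): 4,
    ("benthic", "coastal"): 8,
    ("benthic", "deep_seafloor"): 8,
    ("benthic", "vent"): 4,
}


def small_params(**overrides) -> SimulationParams:
    """Scaled-down defaults: same structure, desk-scale sizes."""
    kw = dict(
        n_otus_pool=800,
        n_samples=dict(SMALL_GROUP_SIZES),
        sequencing_depth=1000.0,
        # well-annotated taxonomy so rank aggregation keeps all samples
        assigned_fractions={
            "phylum": 0.95, "class": 0.85, "order": 0.7,
            "family": 0.6, "genus": 0.5,
        },
        seed=0,
    )
    kw.update(overrides)
    return SimulationParams(**kw)


@pytest.fixture
def tiny_table() -> OtuTable:
    return OtuTable(["s1", "s2"], ["o1", "o2", "o3"], [[1, 0, 2], [0, 3, 0]])


@pytest.fixture
def tiny_metadata() -> SampleMetadata:
    df = pd.DataFrame(
        {
            "latitude": [54.1, -10.0],
            "longitude": [7.9, 120.0],
            "water_depth": [30.0, 3000.0],
            "distance_to_coast": [12.0, 500.0],
            "sample_depth_kind": ["water", "sediment"],
            "special_habitat": ["none", "none"],
            "date": ["2003-06-14", "2004-06-14"],
            "longhurst_productivity": [3, 1],
            "fisheries_class": [2, 4],
        },
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )
    return SampleMetadata(df)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_community(small_params())


@pytest.fixture(scope="session")
def small_realms(small_dataset):
    return small_dataset.metadata.classify()["realm"]
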