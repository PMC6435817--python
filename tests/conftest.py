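import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from agrocore import (
    SimulationParams,
    generate_dataset,
    rarefy,
    relative_abundance,
)
from agrocore.community import DistanceMatrix


def euclidean_dm(points) -> DistanceMatrix:
    points = np.asarray(points, dtype=float)
    ids = [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(ids, squareform(pdist(points)))


@pytest.fixture(scope="session")
def default_survey():
    """One synthetic survey at default study conditions, rarefied."""
    params = SimulationParams(seed=7)
    table, meta, taxonomy, truth = generate_dataset(params)
    rare = rarefy(table, 10_000, seed=7)
    relab = relative_abundance(rare)
    return {
        "params": params,
        "table": table,
        "meta": meta,
        "taxonomy": taxonomy,
        "truth": truth,
        "rare": rare,
        "relab": relab,
    }


@pytest.fixture
def tiny_counts():
    counts = np.array(
        [[5, 3, 2, 0], [1, 1, 1, 1], [0, 0, 7, 3]], dtype=np.int64
    )
    from agrocore import OtuTable

    return OtuTable(["s1", "s2", "s3"], ["o1", "o2", "o3", "o4"], counts)
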