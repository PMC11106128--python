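import numpy as np
import pandas as pd
import pytest

import spotweave as sw


@pytest.fixture(scope="session")
def default_sim():
    """Default-configuration spatial dataset with planted truth (seed 1)."""
    cfg = sw.SimConfig(seed=1)
    expr, meta, truth = sw.simulate_spatial(cfg)
    return cfg, expr, meta, truth


@pytest.fixture(scope="session")
def wgcna_result(default_sim):
    """Full co-expression stage run once on the default dataset."""
    _, expr, meta, _ = default_sim
    return sw.run_wgcna(sw.normalize_log(expr), meta)


@pytest.fixture(scope="session")
def ncrna_sim(default_sim):
    cfg, _, _, _ = default_sim
    tmap_dict, bulk, truth = sw.simulate_ncrna(cfg)
    return sw.TargetMap.from_dict(tmap_dict), bulk, truth


@pytest.fixture()
def tiny_expr():
    """3 spots x 2 genes counts matrix with metadata."""
    counts = np.array([[1.0, 3.0], [0.0, 2.0], [5.0, 0.0]])
    ids = ["s0", "s1", "s2"]
    expr = sw.ExpressionMatrix(counts, ids, ["gA", "gB"], layer="counts")
    meta = sw.SpotMetadata(
        pd.DataFrame(
            {"cluster": [0, 0, 1], "condition": ["N", "A", "N"], "day": 14,
             "x": [0.0, 1.0, 2.0], "y": 0.0},
            index=ids,
        )
    )
    return expr, meta
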