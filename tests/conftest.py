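import numpy as np
import pandas as pd
import pytest

import adaptscape as a


@pytest.fixture(scope="session")
def small_fixture():
    """A compact landscape: 12x12 cells, 60 trees at 6 sites, 158 loci."""
    cfg = a.LandscapeConfig(
        n_cells_x=12, n_cells_y=12, n_individuals=60, n_sites=6,
        n_neutral_loci=150, n_adaptive_loci=8, missing_rate=0.05, seed=42,
    )
    gm, truth, coords, grids = a.simulate_fixture(cfg)
    return cfg, gm, truth, coords, grids


@pytest.fixture(scope="session")
def fitted_engines(small_fixture):
    """All three offset engines fitted on the true adaptive loci."""
    cfg, gm, truth, coords, grids = small_fixture
    gm = a.impute_major(gm)
    env = a.extract_at_points(grids["recent"], coords)[list(cfg.variables)]
    idx = [int(np.flatnonzero(gm.variants["id"] == l)[0]) for l in truth.adaptive_locus_ids]
    cand = pd.DataFrame(
        gm.dosages[:, idx], columns=truth.adaptive_locus_ids, index=env.index
    )
    sites = gm.samples["site"].tolist()
    models = {
        "gf": a.fit_engine("gf", cand, env, seed=1, n_trees=100),
        "rda": a.fit_engine("rda", cand, env, n_axes=2),
        "gdm": a.fit_engine("gdm", cand, env, sites=sites),
    }
    grids_std, _ = a.standardize(grids)
    return models, grids_std
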