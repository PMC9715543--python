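import pandas as pd
import pytest

from fdforest.simulator import SimulationConfig, run_simulation


@pytest.fixture(scope="session")
def small_run():
    """A small reference-climate run shared across read-only tests."""
    cfg = SimulationConfig(n_patches=60, seed=101)
    return run_simulation(cfg, scenario="reference")


@pytest.fixture(scope="session")
def small_records(small_run):
    """Survival records labelled from the shared small run."""
    from fdforest.cohort import drop_degenerate_records, label_survival
    from fdforest.diversity import snapshot_indices

    res = small_run
    tr0 = res.trees_at(res.t0_year)
    div = snapshot_indices(tr0)
    rec = label_survival(tr0, res.trees_at(res.t1_year),
                         res.patches_at(res.t0_year), div)
    rec, _ = drop_degenerate_records(rec)
    return rec


def build_mixed_pure_patches(n_rep: int, seed: int) -> pd.DataFrame:
    """Density-matched pure vs mixed-phenology initial communities."""
    from fdforest.planted import make_mixed_pure_communities

    return make_mixed_pure_communities(n_rep, seed=seed)
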