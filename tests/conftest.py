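import numpy as np
import pandas as pd
import pytest

from eggchamber import morphometrics as mm
from eggchamber import synthetic_data as sd


@pytest.fixture(scope="session")
def noise_free_config():
    return sd.GeneratorConfig(seed=0, noise_cv=0.0)


@pytest.fixture(scope="session")
def wt_cohort_table():
    """Measured wild-type cohort (n=120, default noise) used across tests."""
    cfg = sd.GeneratorConfig(seed=0, n_chambers=120)
    chambers = sd.generate_cohort(cfg)
    return mm.measure_cohort(chambers)


@pytest.fixture(scope="session")
def wt_embedding(wt_cohort_table):
    """Standardize + PCA + UMAP of the session wild-type cohort."""
    from eggchamber import embedding as emb

    return emb.embed_cohort(wt_cohort_table)


@pytest.fixture(scope="session")
def wt_cohort_500():
    """Default-configuration wild-type cohort at the full study size."""
    cfg = sd.GeneratorConfig(seed=0, n_chambers=500)
    return mm.measure_cohort(sd.generate_cohort(cfg))


@pytest.fixture(scope="session")
def fc_scenario_runs():
    """Chamber-scale 14-cell runs of all four FC scenarios (seed 0)."""
    from eggchamber import phasefield_fc as pf
    from eggchamber.affinity_schedules import FC_SCENARIOS

    runs = {}
    for name in FC_SCENARIOS:
        state = pf.init_fc(14, seed=0)
        traj = pf.evolve_fc(state, name, t_end=36.0, sample_every_h=2.0)
        runs[name] = (traj, pf.readout_fc(traj))
    return runs


@pytest.fixture(scope="session")
def germline_scenario_runs():
    """Full-window germline runs of all four scenarios (seed 0)."""
    from eggchamber import phasefield_germline as pg
    from eggchamber.affinity_schedules import GERMLINE_SCENARIOS

    runs = {}
    for name in GERMLINE_SCENARIOS:
        state = pg.init_germline(seed=0)
        traj = pg.evolve_germline(state, name, t_end=36.0, sample_every_h=1.5)
        runs[name] = pg.readout_germline(traj).as_frame()
    return runs
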