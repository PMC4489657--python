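import numpy as np
import pytest

import turnoverkit as tk


@pytest.fixture(scope="session")
def schedule_23_20():
    """Measured-degradation schedule: half-life 23 min at t=0, 20 min at 160 min."""
    return tk.build_linear_schedule(23.0, 20.0, 160.0, 400.0)


@pytest.fixture(scope="session")
def schedule_23_91():
    """Best-fit-like schedule: half-life falls from 23 min to 9.1 min at 160 min."""
    return tk.build_linear_schedule(23.0, 9.1, 160.0, 400.0)


@pytest.fixture(scope="session")
def grid_0_400():
    return np.arange(0.0, 401.0, 50.0)


@pytest.fixture(scope="session")
def noisefree_scenario(tmp_path_factory):
    """Full synthetic study with all measurement noise switched off."""
    outdir = tmp_path_factory.mktemp("noisefree")
    cfg = {"noise": {"densitometry_cv": 0.0, "ct_jitter_sd_cycles": 0.0},
           "sampling": {"n_replicates": 1}}
    return tk.generate_scenario(cfg, outdir=outdir, seed=0), outdir


@pytest.fixture(scope="session")
def noisy_scenario(tmp_path_factory):
    """Full synthetic study at the default noise levels (CV 10%, 0.2 cycles)."""
    outdir = tmp_path_factory.mktemp("noisy")
    return tk.generate_scenario(outdir=outdir, seed=11), outdir
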