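import numpy as np
import pandas as pd
import pytest

from famet import (SimConfig, build_means_table, fit_all_trials, fit_fa,
                   simulate_met)


@pytest.fixture(scope="session")
def small_study():
    """One small unbalanced MET study shared across test modules."""
    cfg = SimConfig(m=40, s=6, k_true=2, reps=2, seed=11, missing_cell_rate=0.1)
    data, truth = simulate_met(cfg)
    return cfg, data, truth


@pytest.fixture(scope="session")
def small_fit(small_study):
    """Stage-1 + FA(2) fit of the shared study."""
    cfg, data, truth = small_study
    fits = fit_all_trials(data, seed=11)
    means = build_means_table(fits)
    fit = fit_fa(means, 2, stage2_resid="fixed", seed=11)
    return means, fit, truth


@pytest.fixture()
def rcbd_records():
    """Complete balanced RCBD plot records for one trial (8 genotypes x 3 reps)."""
    rng = np.random.default_rng(5)
    m, r = 8, 3
    g_eff = rng.normal(0, 2.0, m)
    r_eff = np.array([-1.5, 0.2, 1.3])  # clearly separated blocks
    rows = []
    for i in range(m):
        for j in range(r):
            rows.append({"environment": "2020.ERU.NH", "genotype": f"G{i:02d}",
                         "replicate": j + 1,
                         "value": 20.0 + g_eff[i] + r_eff[j] + rng.normal(0, 1.5)})
    return pd.DataFrame(rows)


def align_truth(fit_envs, truth):
    """Permutation aligning SimTruth (generation order) to fitted env order."""
    return [truth.environments.index(e) for e in fit_envs]
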