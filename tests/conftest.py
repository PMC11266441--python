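import numpy as np
import pandas as pd
import pytest

import metboost
from metboost.synthetic import SimConfig, VarianceComponents


@pytest.fixture(scope="session")
def small_study():
    """A compact three-year study exercising every layer (205 hybrids)."""
    cfg = SimConfig(
        seed=3,
        n_parents=40,
        n_markers=400,
        n_environments_per_year=(2, 5, 5),
        field_rows=14,
        field_cols=12,
        env_hybrid_frac=0.5,
    )
    return metboost.generate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """The default-size study (755 hybrids, 30 environments)."""
    return metboost.generate_study(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_blues(small_study):
    from metboost import trials

    blues, diagnostics, fits = trials.fit_all_trials(small_study.plot_table)
    return blues, diagnostics, fits


@pytest.fixture()
def balanced_rcbd():
    """Balanced 2-rep RCBD toy: 4 hybrids x 2 reps with known cell effects."""
    rng = np.random.default_rng(7)
    hybrids = [f"H{i}" for i in range(4)]
    rows = []
    for rep in (1, 2):
        for i, h in enumerate(hybrids):
            rows.append(
                {
                    "Env": "E_2020",
                    "Hybrid": h,
                    "Replicate": rep,
                    "Block": 1 + i // 2,
                    "Row": 1 + i % 2,
                    "Col": rep,
                    "Yield_Mg_ha": 10.0 + 0.5 * i + 0.3 * (rep - 1) + rng.normal(0, 0.1),
                }
            )
    return pd.DataFrame(rows)


def zero_vc(**overrides):
    base = dict(
        v_g_add=0.0, v_g_dom=0.0, v_env=0.0, v_gxe=0.0,
        v_block=0.0, v_row=0.0, v_col=0.0, v_resid=0.0,
    )
    base.update(overrides)
    return VarianceComponents(**base)
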