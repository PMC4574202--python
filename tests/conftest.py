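import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cafeqg.cafe_io import adjust_consumption, summarize_lines
from cafeqg.simulate import SimulationConfig, simulate_study

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study():
    """One default-scale simulated study shared across tests."""
    cfg = SimulationConfig(seed=11, n_variants=300)
    dataset, panel = simulate_study(cfg)
    adjusted = adjust_consumption(dataset.vials, dataset.controls)
    line_table = summarize_lines(adjusted)
    return dict(
        config=cfg,
        dataset=dataset,
        panel=panel,
        adjusted=adjusted,
        line_table=line_table,
    )


@pytest.fixture()
def toy_vials():
    """A tiny hand-checkable vial table (already adjusted intakes)."""
    rows = []
    data = {
        ("A", "F"): [1.5, 2.0, 2.5],
        ("A", "M"): [1.0, 1.5, 2.0],
        ("B", "F"): [3.0, 3.0, 3.0],
        ("B", "M"): [2.0, 2.5, 3.0],
    }
    for (line, sex), vals in data.items():
        for i, v in enumerate(vals):
            rows.append(dict(line=line, sex=sex, replicate=i + 1, intake=v))
    return pd.DataFrame(rows)


def balanced_panel(rng, n_lines=30, n_reps=4, s_l=4.0, s_sl=1.0, s_e=6.0,
                   mean=12.0, sex_effect=0.9):
    """Direct balanced two-way draw used by oracle tests (bypasses the
    full generator so truth structure is transparent)."""
    rows = []
    L = rng.normal(0, np.sqrt(s_l), n_lines)
    SL = rng.normal(0, np.sqrt(s_sl), (n_lines, 2))
    for i in range(n_lines):
        for j, sex in enumerate(("F", "M")):
            mu = mean + (sex_effect / 2 if sex == "F" else -sex_effect / 2)
            vals = mu + L[i] + SL[i, j] + rng.normal(0, np.sqrt(s_e), n_reps)
            for r, v in enumerate(vals):
                rows.append(dict(line=f"l{i:03d}", sex=sex, replicate=r + 1,
                                 intake=float(v)))
    return pd.DataFrame(rows)
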