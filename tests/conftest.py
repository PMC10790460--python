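import numpy as np
import pandas as pd
import pytest

import vaxequity as vx
from vaxequity.simulate import DoseEffects


@pytest.fixture(scope="session")
def default_sim():
    """One medium population under the default planted structure,
    shared by the identity/metric tests."""
    cfg = vx.SimConfig(n_children=8000, seed=42)
    pop = vx.generate_population(cfg)
    outcomes = vx.derive_outcomes(pop, cfg.schedule)
    return cfg, pop, outcomes


def equal_access_config(n: int, seed: int, coverage: float = 0.7) -> vx.SimConfig:
    """No-inequity DGP: every dose's receipt probability is flat across
    all covariate strata (child-level noise only)."""
    sched = vx.uganda_epi_schedule()
    intercept = float(np.log(coverage / (1 - coverage)))
    effects = {name: DoseEffects(intercept=intercept) for name in sched.dose_names}
    return vx.SimConfig(n_children=n, seed=seed, effects=effects, schedule=sched)


def manual_population(n: int, seed: int) -> pd.DataFrame:
    """Covariate table built directly (no generator), for tests that
    plant outcomes by hand."""
    rng = np.random.default_rng(seed)
    score = rng.standard_normal(n)
    pop = pd.DataFrame({
        "child_id": np.arange(n),
        "age_months": rng.integers(0, 60, n),
        "sex": rng.choice(["female", "male"], n),
        "region": rng.choice(["central", "eastern", "northern", "western"], n),
        "residence": rng.choice(["urban", "rural"], n, p=[0.3, 0.7]),
        "maternal_education": rng.choice(["none", "primary", "secondary+"], n),
        "insured": rng.choice(["yes", "no"], n, p=[0.05, 0.95]),
        "weight": np.ones(n),
        "ses_score": score,
    })
    pop["ses_quintile"] = vx.weighted_quintiles(score)
    return pop
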