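import pandas as pd
import pytest
from hypothesis import settings

from batmodel.model_core import ModelParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def fitted_params() -> ModelParams:
    """The high-probability group parameter set used throughout the analyses."""
    return ModelParams(pi=0.88, beta_low=0.92, beta_high=0.9998, mu=360.0, sigma_rt=100.0)


@pytest.fixture
def tiny_trial_table() -> pd.DataFrame:
    """Two-subject, hand-enumerable trial table (one prime, two sessions)."""
    rows = []
    sessions = {
        # subject 1: session 1 [1,1,0,1,1], session 3 [1,0,1,1]
        (1, 1): ([1, 1, 0, 1, 1], [800.0, 820.0, 900.0, 1500.0, 840.0]),
        (1, 3): ([1, 0, 1, 1], [850.0, 950.0, 1600.0, 870.0]),
        # subject 2: session 1 [1,1,1], session 3 [0, 1, 1]
        (2, 1): ([1, 1, 1], [700.0, 720.0, 740.0]),
        (2, 3): ([0, 1, 1], [900.0, 1400.0, 760.0]),
    }
    for (subject, session), (outcomes, rts) in sessions.items():
        for idx, (b, y) in enumerate(zip(outcomes, rts), start=1):
            rows.append(
                {
                    "subject_id": subject,
                    "prime": "stupid",
                    "session": session,
                    "trial_index": idx,
                    "trial_type": "bivalent",
                    "outcome": b,
                    "rt_ms": y,
                    "latent_c": pd.NA,
                }
            )
    table = pd.DataFrame(rows)
    table["latent_c"] = table["latent_c"].astype("Int64")
    return table
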