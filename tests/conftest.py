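import numpy as np
import pytest

import cullwelfare as cw
from cullwelfare.mcmc import SamplerSettings


@pytest.fixture(scope="session")
def fast_settings() -> SamplerSettings:
    """Short chains for unit tests; long enough for ~1e-2 Monte-Carlo error."""
    return SamplerSettings(n_chains=4, n_draws=1500, n_burn=800, seed=7)


@pytest.fixture(scope="session")
def trial_data():
    """The packaged trial-like dataset (390 animals, 17 sorties)."""
    enc, pm = cw.simulate_trial()
    return enc, pm


@pytest.fixture(scope="session")
def trial_encounters(trial_data):
    return trial_data[0]


@pytest.fixture(scope="session")
def trial_postmortem(trial_data):
    return trial_data[1]


@pytest.fixture
def small_encounters():
    """One well-formed record per ammunition arm, one sortie each."""
    recs = []
    for i, ammo in enumerate(cw.Ammo, start=1):
        recs.append(
            cw.EncounterRecord(
                animal_id=f"A{i:03d}",
                sortie_id=i,
                group_id=i,
                ammo=ammo,
                ct_s=30.0 + i,
                tti_s=5.0 * i,
                tti_censored=(i == 2),
                shots_fired=2,
                outcome=cw.Outcome.INSENSIBLE_GT_1S,
                sex_age=cw.SexAge.ADULT_M,
            )
        )
    return recs
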