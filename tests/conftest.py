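import numpy as np
import pytest

from thermovar.synth import (
    SimConfig,
    generate_nightly_cohort,
    generate_participant,
    make_participants,
)


@pytest.fixture(scope="session")
def nightly_cohort():
    """Nightly-resolution study cohort: 30 cyclic / 30 acyclic females /
    30 males, 180 nights, cycle amplitude 0.3 deg C, nightly noise 0.1 deg C."""
    cfg = SimConfig(
        n_per_group={"cyclic_female": 30, "acyclic_female": 30, "male": 30},
        n_days=180,
        seed=0,
    )
    roster, nightly = generate_nightly_cohort(cfg)
    return cfg, roster, nightly


@pytest.fixture(scope="session")
def minute_participant():
    """One cyclic participant's minute-level stream + nightly summaries."""
    cfg = SimConfig(
        n_per_group={"cyclic_female": 1, "acyclic_female": 1, "male": 1},
        n_days=40,
        seed=0,
    )
    roster = make_participants(cfg)
    p = next(r for r in roster if r.category == "cyclic_female")
    mdf, ndf = generate_participant(p, cfg)
    return cfg, p, mdf, ndf


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
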