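import numpy as np
import pytest

from partbias import participation, popsim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cohort_with_participation():
    """A mid-size cohort with sex-differential participation attached."""
    cfg = popsim.PopulationConfig(20_000, 40, maf=(0.2, 0.5), seed=42)
    cohort = popsim.simulate_cohort(cfg)
    b_f, b_m = participation.draw_participation_effects(
        cohort.mafs, 0.0, 0.2, scenario="sex_differential", seed=43
    )
    model = participation.ParticipationModel(
        pi_female=0.1, pi_male=0.1, b_female=b_f, b_male=b_m,
        h2_male=0.2, scenario="sex_differential",
    )
    model = participation.calibrate_model(cohort, model)
    participation.simulate_participation(cohort, model, seed=44)
    return cohort, model
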