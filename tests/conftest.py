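import pytest

import meropkpd as m


@pytest.fixture(scope="session")
def patients():
    return m.load_patients()


@pytest.fixture(scope="session")
def pk():
    return m.load_pk()


@pytest.fixture(scope="session")
def noise_free_profile():
    """Exact one-compartment first-dose profile on the 8-point schedule."""
    cl, vd = 7.7, 22.6
    c = m.single_dose_conc(list(m.STUDY_SCHEDULE), cl, vd, 1000.0, 0.5)
    return m.ConcentrationTimeProfile(
        "truth", 1000.0, 0.5, tuple(zip(m.STUDY_SCHEDULE, c))
    ), cl, vd
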