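import pytest

from ludose import pipeline, synthetic


@pytest.fixture(scope="session")
def default_patient():
    """Canonical virtual patient: fixed 7400 MBq, default kinetics."""
    return synthetic.generate_patient({"administered_mbq": 7400.0}, seed=1)


@pytest.fixture(scope="session")
def noiseless_scans(default_patient):
    return synthetic.simulate_planar_scans(default_patient, noise=False, seed=3)


@pytest.fixture(scope="session")
def noiseless_samples(default_patient):
    return synthetic.simulate_blood_samples(default_patient, noise=False, seed=2)


@pytest.fixture(scope="session")
def noiseless_config():
    return pipeline.RunConfig(noise=False, vary_patients=False,
                              administered_mbq=7400.0, n_patients=1)


@pytest.fixture(scope="session")
def toy_smatrix(noiseless_config):
    return noiseless_config.s_matrix()
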