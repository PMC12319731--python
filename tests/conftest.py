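import numpy as np
import pytest

import brainstates as bs
import brainstates.leida as leida


@pytest.fixture(scope="session")
def small_cohort():
    """10 subjects, 40 regions, 200 timepoints, planted K=3."""
    return bs.generate_cohort(n_subjects=10, n_regions=40, n_timepoints=200,
                              n_states=3, noise_sd=0.3, seed=11)


@pytest.fixture(scope="session")
def recovered_model(small_cohort):
    """LEiDA run over the small cohort: (pooled, index, fitted model)."""
    eig = {sid: leida.subject_eigenvectors(ts)
           for sid, ts in small_cohort.timeseries.items()}
    pooled, index = leida.pool_eigenvectors(eig)
    model = leida.LeidaStates(k_range=(2, 5), n_restarts=10, random_state=0).fit(pooled)
    return pooled, index, model


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
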