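import numpy as np
import pytest

from aaagrowth.data import Measurement, Subject
from aaagrowth.model import fit_growth_model
from aaagrowth.simulate import GeneratorConfig, TruthParams, simulate_cohort


def make_subject(times, values, subject_id="s0", covariates=None, termination=None):
    return Subject(
        subject_id=subject_id,
        measurements=tuple(Measurement(time=t, value=v) for t, v in zip(times, values)),
        covariates=covariates or {},
        termination=termination,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Model-faithful cohort (no entry selection, normal baseline), n=120."""
    cfg = GeneratorConfig(
        n_subjects=120, seed=1234, entry="all", truth=TruthParams()
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """A quick but usable linear-model fit shared across prediction tests."""
    draws, diag = fit_growth_model(
        small_cohort.dataset, n_chains=2, n_iter=900, n_burnin=300, seed=99,
        compute_dic=False,
    )
    return draws, diag
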