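import warnings

import numpy as np
import pytest

from patlak_gfr import (
    PipelineConfig,
    default_model,
    run_subject_pipeline,
)
from patlak_gfr.synthetic_data import default_noise, default_truth, make_subject


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def noiseless_subject(truth):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_subject(truth)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_subject):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_subject_pipeline(
            curves=noiseless_subject.si_curves,
            geometry=noiseless_subject.geometry,
            subject=noiseless_subject.subject,
            calibration=noiseless_subject.calibration,
        )


def run_quiet(subject, config: PipelineConfig | None = None):
    """Run the pipeline with warnings suppressed (noisy loops)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_subject_pipeline(
            curves=subject.si_curves,
            geometry=subject.geometry,
            subject=subject.subject,
            calibration=subject.calibration,
            config=config,
        )


@pytest.fixture(scope="session")
def noisy_truth(truth):
    from dataclasses import replace

    return replace(truth, noise=default_noise())
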