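import dataclasses
import warnings

import numpy as np
import pytest

from affectrecall import build_canonical_design, synthdata

# pingouin warns about epsilon accuracy in >2-level two-way within designs;
# the GG-corrected p-values are still the quantity under test.
warnings.filterwarnings("ignore", message="Epsilon values might be innaccurate")


@pytest.fixture(scope="session")
def study1():
    return build_canonical_design("study1")


@pytest.fixture(scope="session")
def study2():
    return build_canonical_design("study2")


@pytest.fixture(scope="session")
def pupil_cohort():
    """Small lab-style cohort with pupil traces, shared across pupil tests.

    Scaled down from the canonical recording (100 Hz instead of 500 Hz,
    120 preference trials) to keep the suite fast; the generator is the
    same code path.
    """
    design = build_canonical_design("study1")
    design.preference_spec = dataclasses.replace(design.preference_spec,
                                                 n_trials=120)
    spec = synthdata.PupilTraceSpec(fs=100.0)
    return synthdata.simulate_population(design, 8, seed=42, with_pupil=True,
                                         trace_spec=spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
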