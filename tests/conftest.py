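"""Shared fixtures: small synthetic cohorts and reusable models.

Everything is generated at test time with fixed seeds; session scope keeps
the expensive end-to-end objects shared across test modules.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from microdyn import (
    CohortSpec,
    MarkovSpec,
    MicrostateModel,
    make_templates,
    simulate_cohort,
    simulate_label_sequence,
    synthesize_recording,
)
from microdyn.preprocess import preprocess
from microdyn.synthetic import uniform_transition_matrix


@pytest.fixture(scope="session")
def templates91():
    return make_templates(91, seed=1)


@pytest.fixture(scope="session")
def true_model(templates91):
    """Microstate model holding the planted maps themselves."""
    maps = np.stack([t.values for t in templates91])
    return MicrostateModel(maps=maps, gev=1.0, k=4, n_restarts=0, seed=0)


@pytest.fixture(scope="session")
def uniform_markov():
    return MarkovSpec(np.full(4, 80.0), uniform_transition_matrix(4), seed=3)


@pytest.fixture(scope="session")
def noiseless_subject(templates91, uniform_markov):
    """A 60-s noiseless recording plus its generator labels."""
    labels = simulate_label_sequence(uniform_markov, 250.0, 15000)
    rec = synthesize_recording(labels, templates91, noise_sd=0.0, seed=5)
    return rec, labels


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-subject, 40-s cohort at default noise and planted effects."""
    spec = CohortSpec(n_hc=4, n_adhd_c=3, n_adhd_i=3, duration_s=40.0, seed=42)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_clean(small_cohort):
    from dataclasses import replace

    from microdyn.preprocess import PreprocessConfig

    cfg = PreprocessConfig(keep_s=40.0)
    return [preprocess(rec, cfg) for rec in small_cohort.recordings]
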