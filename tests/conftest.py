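"""Shared fixtures: one synthetic study reused across the suite.

Session-scoped so the (deterministic) generation and model fits run once.
"""

from __future__ import annotations

import warnings

import pandas as pd
import pytest

from painecg.cascade import TrainConfig, fit_cascade
from painecg.features import build_feature_table
from painecg.pipeline import RunConfig, build_study_table
from painecg.preprocess import segment_windows
from painecg.synthdata import generate_session, null_effect


@pytest.fixture(scope="session", autouse=True)
def _quiet_warnings():
    warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def default_session():
    """One default-protocol session with the standard autonomic effect."""
    return generate_session(seed=3)


@pytest.fixture(scope="session")
def default_windows(default_session):
    return segment_windows(default_session, session_id="fix")


@pytest.fixture(scope="session")
def default_feature_table(default_windows):
    return build_feature_table(default_windows)


@pytest.fixture(scope="session")
def study_table():
    """Three-session study with pain effects on (strongly separable)."""
    return build_study_table(RunConfig(seed=101, n_sessions=3))


@pytest.fixture(scope="session")
def fitted_cascade(study_table):
    model, test = fit_cascade(study_table, TrainConfig(seed=7, n_trees=80))
    return model, test


@pytest.fixture(scope="session")
def null_study_table():
    """Negative-control study: CoVAS labels exist but no autonomic modulation."""
    cfg = RunConfig(seed=202, n_sessions=3, effect=null_effect(covas_noise_sd=3.0))
    return build_study_table(cfg)
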