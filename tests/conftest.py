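"""Shared fixtures: small synthetic sessions generated once per test run.

Problem sizes here are deliberately smaller than the study-scale generator
defaults (fewer trials, shorter probes) so the full suite stays fast; tests
that need study-scale statistics build their own sessions.
"""

import numpy as np
import pytest

from cheeseboard.synthetic import SynthConfig, generate_session


@pytest.fixture(scope="session")
def learning_session():
    cfg = SynthConfig(seed=11, n_trials=12)
    return generate_session(cfg, kind="learning")


@pytest.fixture(scope="session")
def probe_session():
    cfg = SynthConfig(seed=12, probe_duration_s=420)
    return generate_session(cfg, kind="post_probe")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
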