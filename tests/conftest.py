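import numpy as np
import pytest

from earmotion import simulate as sim


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_quiet_spec(**overrides):
    """Artifact-free, effect-free, jitter-free single-channel cohort spec
    for deterministic recovery tests."""
    spec = sim.quiet_spec(
        channels=("R4a",),
        power_jitter_sd={b: 0.0 for b in sim.CANONICAL_BANDS},
        subband_jitter_sd=0.0,
    )
    import dataclasses

    return dataclasses.replace(spec, **overrides)


@pytest.fixture(scope="session")
def quiet_session():
    """One short artifact-free session shared across tests."""
    spec = make_quiet_spec(
        n_subjects=1,
        videos_per_class=1,
        video_duration_s=20.0,
        baseline_duration_s=20.0,
        seed=7,
    )
    return sim.generate_session(spec, "s01")
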