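"""Shared fixtures: small synthetic sweeps built once per session."""

import numpy as np
import pytest

from dendrospike.synth import SynthSweepConfig, generate_sweep
from dendrospike.synth import scenarios


@pytest.fixture(scope="session")
def di_sweep_noisefree():
    """One DI spike, noise-free, with ground truth."""
    rng = np.random.default_rng(0)
    cfg = scenarios.di_config(rng, seed=0, noise_sd=0.0)
    return generate_sweep(cfg)


@pytest.fixture(scope="session")
def di_sweep_noisy():
    rng = np.random.default_rng(1)
    cfg = scenarios.di_config(rng, seed=1, noise_sd=0.3)
    return generate_sweep(cfg)


@pytest.fixture(scope="session")
def slow_adp_sweep():
    """Initiating bAP + slow ADP driving a 3-AP burst, default noise."""
    rng = np.random.default_rng(3)
    cfg = scenarios.slow_adp_config(rng, seed=3, noise_sd=0.3)
    return generate_sweep(cfg)


@pytest.fixture(scope="session")
def fast_adp_sweep_noisefree():
    rng = np.random.default_rng(2)
    cfg = scenarios.fast_adp_config(rng, seed=2, noise_sd=0.0)
    return generate_sweep(cfg)


@pytest.fixture(scope="session")
def flat_sweep():
    """No events, default noise."""
    cfg = SynthSweepConfig(step_amplitude=300.0, seed=7, noise_sd=0.3)
    return generate_sweep(cfg)


def short_sweep_config(step_pa, schedule, seed, noise_sd=0.3):
    """A compact sweep (300 ms step) for high-volume simulation tests."""
    return SynthSweepConfig(step_amplitude=step_pa, event_schedule=schedule,
                            seed=seed, noise_sd=noise_sd,
                            pre_ms=50.0, step_duration=300.0, post_ms=50.0)
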