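import numpy as np
import pytest

from crabloom import (
    AnalysisConfig,
    BehaviorGenParams,
    SpikeTrain,
    experiment1_treatments,
    gen_escape_trials,
)


@pytest.fixture
def exp1_treatments():
    return experiment1_treatments()


@pytest.fixture
def fast_config():
    """Analysis thresholds scaled for quick test runs."""
    return AnalysisConfig(n_perm=999, n_boot=400, dt=0.005, seed=7)


@pytest.fixture
def selective_trials(exp1_treatments):
    """40 crabs x 1 block under selective attention, default conditions."""
    params = BehaviorGenParams(attention_mode="selective", seed=11)
    return gen_escape_trials(params, exp1_treatments, 40, 1)


def poisson_train(rate, span, seed, **kwargs):
    """Homogeneous Poisson spike train over (start, end)."""
    rng = np.random.default_rng(seed)
    start, end = span
    n = rng.poisson(rate * (end - start))
    return np.sort(rng.uniform(start, end, size=n))


@pytest.fixture
def step_train():
    """Baseline 5 Hz for 60 s, stepping to 30 Hz at t = -3 s."""

    def make(seed):
        base = poisson_train(5.0, (-63.0, -3.0), seed)
        high = poisson_train(30.0, (-3.0, 0.0), seed + 10_000)
        return SpikeTrain(
            spike_times=np.concatenate([base, high]),
            trial_span=(-6.0, 0.0),
            spont_span=(-63.0, -6.0),
        )

    return make
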