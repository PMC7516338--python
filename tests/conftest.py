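import numpy as np
import pytest

from retroeval.core import MomentSequence, RatedTrial
from retroeval.synthetic_data import GroundTruth, ParticipantConfig, generate_participant


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_participant():
    """One synthetic participant under the default study conditions."""
    return generate_participant(ParticipantConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_wp_participant():
    """A participant whose ratings are an exact windowed-preference readout."""
    cfg = ParticipantConfig(
        seed=17,
        ground_truth=GroundTruth(model="windowed_preference", L=10),
        rating_noise_sd=0.0,
        discretize=False,
    )
    return generate_participant(cfg)


def make_trials(seqs, ys, task="continued"):
    return [
        RatedTrial(MomentSequence(x), float(y), task)
        for x, y in zip(seqs, ys)
    ]


@pytest.fixture
def random_seq4_trials(rng):
    """96 length-4 trials with utilities drawn uniformly from [1, 9]."""

    def build(target_fn, noise_sd=0.0, n=96):
        trials = []
        for i in range(n):
            x = rng.uniform(1.0, 9.0, 4)
            y = target_fn(x) + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            trials.append(
                RatedTrial(MomentSequence(x), float(np.clip(y, 1, 9)), "seq4")
            )
        return trials

    return build
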