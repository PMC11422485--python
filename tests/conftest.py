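import numpy as np
import pytest

from wormspaces import posture, synth


@pytest.fixture(scope="session")
def rendered_worm():
    """A short rendered worm sequence with ground truth."""
    frames, truth = synth.simulate_worm_frames(n_frames=60, seed=11)
    return frames, truth


@pytest.fixture(scope="session")
def processed_worm(rendered_worm):
    frames, truth = rendered_worm
    result = posture.process_frames(frames, store_midlines=True)
    return result, truth


@pytest.fixture(scope="session")
def planted_pool():
    """Rank-3 window pool with tiny noise."""
    X, truth = synth.simulate_planted_rank(200, 3, snr=1000, n_features=60,
                                           seed=21)
    return X, truth


def match_head_first(midline, truth_midline):
    """Orient a detected midline to the truth's head-first order."""
    m = np.asarray(midline)
    if ((m[0] - truth_midline[0]) ** 2).sum() > \
            ((m[-1] - truth_midline[0]) ** 2).sum():
        return m[::-1]
    return m
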