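import numpy as np
import pytest

from isfcpipe.preprocess import CleanedSeries
from isfcpipe.synthetic import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_config():
    """6 regions, one coupled pair with a planted group difference."""
    sigma = np.eye(6)
    sigma[0, 1] = sigma[1, 0] = 0.5
    w_nt = np.array([0.9, 0.9, 0.5, 0.5, 0.0, 0.0])
    w_aut = np.array([0.3, 0.3, 0.5, 0.5, 0.0, 0.0])
    return SyntheticConfig(
        n_regions=6,
        n_timepoints=200,
        group_sizes=(5, 5),
        stimulus_correlation=sigma,
        weights_by_group={"NT": w_nt, "AUT": w_aut},
        noise_sd=1.0,
        seed=7,
    )


def make_subjects(n, t, r, rng, group="NT", prefix="sub"):
    """Independent white-noise subjects wrapped as CleanedSeries."""
    return [
        CleanedSeries(
            data=rng.standard_normal((t, r)),
            subject_id=f"{prefix}-{group}{i:02d}",
            group=group,
        )
        for i in range(n)
    ]
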