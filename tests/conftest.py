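import numpy as np
import pytest

from taskdecomp import Trial, TrialSet


def make_trialset(
    n_trials=4,
    n_joints=2,
    n_frames=6,
    release=None,
    seed=0,
    subject="S01",
    day=1,
):
    """Small deterministic TrialSet with alternating labels."""
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n_trials):
        trials.append(
            Trial(
                subject_id=subject,
                day=day,
                trial_index=i + 1,
                label=i % 2,
                angles=rng.normal(size=(n_joints, n_frames)),
                release_frame=release,
            )
        )
    return TrialSet(
        trials=trials, joint_names=[f"j{k}" for k in range(n_joints)]
    )


@pytest.fixture
def tiny_trialset():
    return make_trialset(n_trials=4, n_joints=2, n_frames=6, release=4)
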