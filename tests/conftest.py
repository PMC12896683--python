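import numpy as np
import pandas as pd
import pytest

from sldecode.data import EpochSet, validate_trial_table
from sldecode.synth import DesignConfig, generate_design


def make_trial_table(
    distractor_hemis,
    target_hemis=None,
    session=1,
    block=None,
    high="left",
):
    """Build a minimal valid trial table from a list of hemifield labels."""
    n = len(distractor_hemis)
    if target_hemis is None:
        target_hemis = ["left" if i % 2 == 0 else "right" for i in range(n)]
    if block is None:
        block = [1] * n
    rows = []
    for i in range(n):
        hemi = distractor_hemis[i]
        rows.append(
            {
                "session": session,
                "block": block[i],
                "trial": i + 1,
                "distractor_present": hemi != "absent",
                "distractor_hemifield": hemi,
                "distractor_position": "upper" if hemi != "absent" else "absent",
                "target_hemifield": target_hemis[i],
                "target_position": "lower",
                "high_prob_hemifield": high,
                "prev_distractor_hemifield": np.nan,
                "prev_target_hemifield": np.nan,
            }
        )
    return validate_trial_table(pd.DataFrame(rows))


@pytest.fixture
def small_epochs():
    """20 trials x 8 sensors x 60 samples of seeded noise at 200 Hz."""
    table = generate_design(
        DesignConfig(
            n_sessions=1, blocks_per_session=1, trials_per_block=20, seed=1
        )
    )
    rng = np.random.default_rng(7)
    data = rng.standard_normal((20, 8, 60))
    times = -0.1 + np.arange(60) / 200.0
    return EpochSet(data=data, times=times, sfreq=200.0, trial_table=table)
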