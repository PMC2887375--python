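import numpy as np
import pytest
from types import SimpleNamespace

from maci import (
    NipalsPCA,
    ScoreTrajectory,
    build_feature_table,
    heel_raise_preset,
    render_sequence,
)
from maci.tracking import track_grid


@pytest.fixture(scope="session")
def heel_bundle():
    """Full-scale three-repetition heel-raise study: rendered once per session.

    420 frames of 128x128 speckle with depth-graded shear, default noise and
    repetition jitter, plus the fitted wavelet-table PCA model.
    """
    spec = heel_raise_preset(seed=1)
    seq, truth = render_sequence(spec)
    table = build_feature_table(seq, n_keep=3000)
    model = NipalsPCA(n_components=2).fit(table.X)
    traj = ScoreTrajectory(model.scores_, frame_rate=seq.frame_rate)
    return SimpleNamespace(
        spec=spec, seq=seq, truth=truth, table=table, model=model, traj=traj
    )


@pytest.fixture(scope="session")
def heel_grid_tracks(heel_bundle):
    """20x20 whole-image grid tracked through the heel-raise sequence."""
    return track_grid(heel_bundle.seq, (20, 20), window=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
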