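import numpy as np
import pandas as pd
import pytest

from flypheno import ethogram
from flypheno.ethogram import INTERVAL


def make_annotations(moving, start=0.0, missing=None):
    """Annotation frame from a boolean moving sequence on the 10-s grid."""
    moving = np.asarray(moving, dtype=bool)
    n = moving.size
    miss = np.zeros(n, dtype=bool) if missing is None else np.asarray(missing, bool)
    ann = pd.DataFrame({
        "interval_start": start + INTERVAL * np.arange(n),
        "moving": moving & ~miss,
        "max_displacement": np.where(moving, 1.0, 0.05),
        "corrected_velocity": np.where(moving, 200.0, 5.0),
        "log_distance": 0.0,
        "distance": np.where(moving, 5.0, 0.1),
        "missing": miss,
    })
    return ann


def make_track(displacements, fps=2.0, fly_id="f0", genotype="wt", **kw):
    """1-D track whose frame-to-frame displacements are as given."""
    x = np.concatenate([[10.0], 10.0 + np.cumsum(displacements)])
    t = np.arange(x.size) / fps
    y = np.full(x.size, 1.5)
    return ethogram.FlyTrack(fly_id=fly_id, genotype=genotype, t=t, x=x, y=y,
                             fps=fps, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def permissive_qc():
    """QC that retains every recording day (for hand-built annotations)."""
    return ethogram.QCResult(fly_id="f0", dead=False, excluded_days=[])
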