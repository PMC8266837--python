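import numpy as np
import pandas as pd
import pytest

from sonoflow.synth import GeneratorConfig, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def short_config():
    """A fast-to-generate configuration: ~2-minute scans, default rates."""
    return GeneratorConfig(
        seed=7, duration_mean=2.0, duration_sd=0.3, duration_bounds=(1.5, 3.0)
    )


@pytest.fixture
def short_session(short_config):
    return simulate_session(short_config, 0)


def gaze_frame(ts, xs, ys, valid=None):
    """Build a gaze DataFrame from explicit sample columns."""
    n = len(ts)
    return pd.DataFrame(
        {
            "t": np.asarray(ts, dtype=float),
            "x": np.asarray(xs, dtype=float),
            "y": np.asarray(ys, dtype=float),
            "valid": np.ones(n, dtype=bool) if valid is None else np.asarray(valid, bool),
        }
    )


def imu_frame(t, gyro, accel, mag):
    """Build an IMU DataFrame from per-sample (or constant) channel values."""
    n = len(t)

    def col(v):
        return np.broadcast_to(np.asarray(v, dtype=float), (n, 3)).copy()

    g, a, m = col(gyro), col(accel), col(mag)
    return pd.DataFrame(
        {
            "t": t,
            "gx": g[:, 0], "gy": g[:, 1], "gz": g[:, 2],
            "ax": a[:, 0], "ay": a[:, 1], "az": a[:, 2],
            "mx": m[:, 0], "my": m[:, 1], "mz": m[:, 2],
        }
    )
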