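"""Shared fixtures: hand-built epoch series and tiny CSV writers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from circalight.io import EpochSeries


def build_series(
    channel_values: dict[str, np.ndarray],
    start: str = "2022-03-21 00:00:00",
    epoch_length: int = 60,
    valid: np.ndarray | None = None,
    participant_id: str = "T001",
    events=None,
) -> EpochSeries:
    n = len(next(iter(channel_values.values())))
    base = {
        "activity_pim": np.zeros(n),
        "wrist_temp": np.full(n, 31.0),
        "lux": np.zeros(n),
        "blue": np.zeros(n),
    }
    base.update({k: np.asarray(v, dtype=float) for k, v in channel_values.items()})
    return EpochSeries(
        participant_id=participant_id,
        start_time=pd.Timestamp(start),
        channels=base,
        valid=np.ones(n, dtype=bool) if valid is None else valid,
        epoch_length=epoch_length,
        events=events or [],
    )


@pytest.fixture
def cosine_series():
    """7 days of 1-min sampling of y(t) = 10 + 3·cos(2π(t−15)/24)."""
    t = np.arange(0, 7 * 24, 1 / 60.0)
    y = 10 + 3 * np.cos(2 * np.pi * (t - 15) / 24)
    return build_series({"activity_pim": y})


@pytest.fixture
def rng():
    return np.random.default_rng(20240321)


def write_epoch_csv(path, rows, header="timestamp,activity_pim,wrist_temp,lux,blue"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path
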