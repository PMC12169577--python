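"""Functional connectivity matrices from residual HbO series.

One symmetric channel x channel Pearson-correlation matrix per condition:
the full run for resting recordings, and per-condition concatenations of
fixed post-onset trial windows for evoked recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import Recording

log = logging.getLogger(__name__)

#: trial window relative to stimulus onset, seconds
EVOKED_WINDOW_S = (0.0, 22.0)


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson-r matrix over retained long channels."""

    condition: str
    channel_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.channel_ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match channel list")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-9):
            raise ValueError("Pearson correlations must lie in [-1, 1]")
        np.fill_diagonal(v, 0.0)
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.channel_ids, columns=self.channel_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, condition: str) -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(condition, list(df.columns), df.to_numpy())


def _pearson_matrix(x: np.ndarray, channel_ids: list[str], condition: str) -> ConnectivityMatrix:
    sd = x.std(axis=0)
    dead = [channel_ids[j] for j in np.flatnonzero(sd == 0)]
    if dead:
        raise ValueError(f"correlation undefined for constant channel(s): {dead}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(condition, list(channel_ids), r)


def resting_connectivity(recording: Recording, min_duration_s: float = 60.0) -> ConnectivityMatrix:
    """Pairwise Pearson r over a full resting run (>= ``min_duration_s``)."""
    if recording.stage != "residual":
        raise ValueError("connectivity is computed on residual series")
    if recording.duration_s < min_duration_s:
        raise ValueError(f"resting run shorter than {min_duration_s:.0f} s")
    return _pearson_matrix(recording.data, recording.channel_ids, "rest")


def evoked_connectivity(
    recording: Recording,
    condition: str,
    window_s: tuple[float, float] = EVOKED_WINDOW_S,
) -> ConnectivityMatrix:
    """Connectivity from concatenated per-trial windows of one condition.

    Each trial contributes ``[onset + window_s[0], onset + window_s[1])``;
    segments are demeaned per channel (so slow between-trial baseline
    offsets do not inflate correlations) and concatenated in temporal order.
    Trials whose window runs past the end of the recording are dropped with
    a logged warning; fewer than two usable trials is an error.
    """
    if recording.stage != "residual":
        raise ValueError("connectivity is computed on residual series")
    t0, t1 = window_s
    n_win = int(np.floor((t1 - t0) * recording.fs))
    segments = []
    for e in recording.events.for_condition(condition):
        i0 = int(round((e.onset_s + t0) * recording.fs))
        if i0 < 0 or i0 + n_win > recording.n_times:
            log.warning(
                "dropping %s trial at t=%.1f s: window exceeds run bounds", condition, e.onset_s
            )
            continue
        seg = recording.data[i0 : i0 + n_win]
        segments.append(seg - seg.mean(axis=0, keepdims=True))
    if len(segments) < 2:
        raise ValueError(f"fewer than 2 usable {condition!r} trials")
    x = np.concatenate(segments, axis=0)
    return _pearson_matrix(x, recording.channel_ids, condition)


def subject_connectivity(
    rest: Recording | None, evoked: Recording | None
) -> dict[str, ConnectivityMatrix]:
    """The three per-participant matrices: rest, auditory, visual."""
    out: dict[str, ConnectivityMatrix] = {}
    if rest is not None:
        out["rest"] = resting_connectivity(rest)
    if evoked is not None:
        for cond in evoked.events.conditions:
            out[cond] = evoked_connectivity(evoked, cond)
    return out
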