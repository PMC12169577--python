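"""Recording container and per-subject metadata.

A :class:`Recording` holds a time x series matrix at one of four processing
stages: raw ``intensity``, ``optical_density``, ``haemoglobin`` or
``residual``.  At the optical stages each channel contributes one series per
wavelength (760 / 850 nm); from the haemoglobin stage on, one series per
chromophore (HbO / HbR, or HbO only after residualization).  The container
is deliberately stage-aware so that each preprocessing operation can assert
its input contract instead of silently mis-applying.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

STAGES = ("intensity", "optical_density", "haemoglobin", "residual")
WAVELENGTHS = ("760", "850")
CHROMOPHORES = ("HbO", "HbR")
CONDITIONS = ("auditory", "visual")


@dataclass(frozen=True)
class Event:
    onset_s: float
    duration_s: float
    condition: str

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.duration_s < 0 or self.onset_s < 0:
            raise ValueError("event onset/duration must be non-negative")


@dataclass
class EventSchedule:
    """Time-sorted, non-overlapping stimulus blocks."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self):
        ev = sorted(self.events, key=lambda e: e.onset_s)
        for a, b in zip(ev, ev[1:]):
            if a.onset_s + a.duration_s > b.onset_s + 1e-9:
                raise ValueError(f"overlapping events at t={a.onset_s} and t={b.onset_s}")
        runs = _run_lengths([e.condition for e in ev])
        if runs and max(runs) > 2:
            raise ValueError("more than two consecutive events share a condition")
        self.events = ev

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def for_condition(self, condition: str) -> list[Event]:
        return [e for e in self.events if e.condition == condition]

    @property
    def conditions(self) -> list[str]:
        return sorted({e.condition for e in self.events})


def _run_lengths(seq: Sequence[str]) -> list[int]:
    runs: list[int] = []
    for i, s in enumerate(seq):
        if i and s == seq[i - 1]:
            runs[-1] += 1
        else:
            runs.append(1)
    return runs


GROUPS = ("control", "unilateral", "bilateral")
SIDES = ("left", "right", "none")


@dataclass
class SubjectMeta:
    """Group label and clinical covariates for one participant."""

    subject_id: str
    group: str = "control"
    tinnitus_side: str = "none"
    thi: float = 0.0
    loudness: float = 0.0
    annoyance: float = 0.0
    duration_years: float = 0.0
    device: str = "scout"
    hearing_left_db: float = 0.0
    hearing_right_db: float = 0.0

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.tinnitus_side not in SIDES:
            raise ValueError(f"unknown tinnitus side {self.tinnitus_side!r}")
        if not 0.0 <= self.thi <= 100.0:
            raise ValueError("THI must be in [0, 100]")
        if (self.group == "unilateral") != (self.tinnitus_side in ("left", "right")):
            raise ValueError("tinnitus_side must be left/right iff group is unilateral")
        if self.duration_years < 0:
            raise ValueError("duration_years must be >= 0")

    @property
    def hearing_asymmetry_db(self) -> float:
        """Left minus right ear threshold difference (dB HL)."""
        return self.hearing_left_db - self.hearing_right_db


@dataclass
class Recording:
    """Time x series data at a declared processing stage.

    ``channel_ids[j]`` and ``bands[j]`` label column ``j`` of ``data``; a
    band is a wavelength ("760"/"850") at optical stages and a chromophore
    ("HbO"/"HbR") from the haemoglobin stage on.
    """

    data: np.ndarray
    fs: float
    stage: str
    channel_ids: list[str]
    bands: list[str]
    events: EventSchedule = field(default_factory=EventSchedule)
    meta: SubjectMeta | None = None
    run_type: str = "rest"  # "rest" | "evoked"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (time x series)")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if len(self.channel_ids) != self.data.shape[1] or len(self.bands) != self.data.shape[1]:
            raise ValueError("channel_ids/bands length must match the number of data columns")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if np.isnan(self.data).any():
            raise ValueError("data contains missing values")
        valid = WAVELENGTHS if self.stage in ("intensity", "optical_density") else CHROMOPHORES
        bad = sorted(set(self.bands) - set(valid))
        if bad:
            raise ValueError(f"bands {bad} invalid for stage {self.stage!r}")

    # -- accessors -------------------------------------------------------
    @property
    def n_times(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.fs

    @property
    def unique_channels(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.channel_ids:
            seen.setdefault(c)
        return list(seen)

    def column(self, channel_id: str, band: str) -> np.ndarray:
        for j, (c, b) in enumerate(zip(self.channel_ids, self.bands)):
            if c == channel_id and b == band:
                return self.data[:, j]
        raise KeyError((channel_id, band))

    def select_band(self, band: str) -> "Recording":
        """Sub-recording with one series per channel for the given band."""
        idx = [j for j, b in enumerate(self.bands) if b == band]
        if not idx:
            raise KeyError(band)
        return replace(
            self,
            data=self.data[:, idx],
            channel_ids=[self.channel_ids[j] for j in idx],
            bands=[band] * len(idx),
        )

    def drop_channels(self, channel_ids) -> "Recording":
        drop = set(channel_ids)
        idx = [j for j, c in enumerate(self.channel_ids) if c not in drop]
        return replace(
            self,
            data=self.data[:, idx],
            channel_ids=[self.channel_ids[j] for j in idx],
            bands=[self.bands[j] for j in idx],
        )

    def with_data(self, data: np.ndarray, stage: str | None = None) -> "Recording":
        return replace(self, data=data, stage=stage or self.stage)
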