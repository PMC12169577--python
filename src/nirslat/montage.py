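"""Optode montage geometry and hemisphere labelling.

A montage is a list of source-detector channels with 3-D optode positions in
head-centred coordinates (metres, x increasing to the subject's right,
y anterior, z superior).  Long channels (~30 mm separation) sample cortex;
short channels (~11 mm) sample scalp/skull systemic physiology and serve as
nuisance regressors.  Hemisphere membership of a channel is a pure function
of the x-coordinate of its source-detector midpoint, with a small midline
band so that truly central channels are assigned to neither hemisphere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

LONG_SEPARATION_M = 0.030
SHORT_SEPARATION_M = 0.011
SEPARATION_TOL_M = 0.002
#: half-width of the midline band: |midpoint x| below this is neither L nor R
MIDLINE_BAND_M = 0.005

REGIONS = ("frontal", "left-temporal", "right-temporal", "occipital")


def hemisphere_of_x(x: float, midline_band: float = MIDLINE_BAND_M) -> str:
    """Hemisphere label ('left' | 'right' | 'midline') for a midpoint x."""
    if x > midline_band:
        return "right"
    if x < -midline_band:
        return "left"
    return "midline"


@dataclass(frozen=True)
class ChannelDef:
    """One source-detector pair."""

    id: str
    source_pos: tuple[float, float, float]
    detector_pos: tuple[float, float, float]
    kind: str  # "long" | "short"
    region: str

    def __post_init__(self):
        if self.kind not in ("long", "short"):
            raise ValueError(f"channel {self.id}: kind must be long|short, got {self.kind!r}")
        if self.region not in REGIONS:
            raise ValueError(f"channel {self.id}: unknown region {self.region!r}")

    @property
    def separation(self) -> float:
        """3-D Euclidean source-detector distance in metres."""
        return float(np.linalg.norm(np.subtract(self.source_pos, self.detector_pos)))

    @property
    def midpoint(self) -> np.ndarray:
        return (np.asarray(self.source_pos) + np.asarray(self.detector_pos)) / 2.0

    @property
    def hemisphere(self) -> str:
        return hemisphere_of_x(float(self.midpoint[0]))


@dataclass
class Montage:
    """An ordered collection of channels with unique ids."""

    channels: list[ChannelDef] = field(default_factory=list)

    def __post_init__(self):
        ids = [c.id for c in self.channels]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate channel ids: {dup}")
        for c in self.channels:
            nominal = LONG_SEPARATION_M if c.kind == "long" else SHORT_SEPARATION_M
            if abs(c.separation - nominal) > SEPARATION_TOL_M:
                raise ValueError(
                    f"channel {c.id}: {c.kind} separation {c.separation * 1e3:.1f} mm "
                    f"outside {nominal * 1e3:.0f} +/- {SEPARATION_TOL_M * 1e3:.0f} mm"
                )

    def __len__(self) -> int:
        return len(self.channels)

    def __getitem__(self, channel_id: str) -> ChannelDef:
        for c in self.channels:
            if c.id == channel_id:
                return c
        raise KeyError(channel_id)

    def __contains__(self, channel_id: str) -> bool:
        return any(c.id == channel_id for c in self.channels)

    @property
    def channel_ids(self) -> list[str]:
        return [c.id for c in self.channels]

    @property
    def long_ids(self) -> list[str]:
        return [c.id for c in self.channels if c.kind == "long"]

    @property
    def short_ids(self) -> list[str]:
        return [c.id for c in self.channels if c.kind == "short"]

    def hemisphere(self, channel_id: str) -> str:
        return self[channel_id].hemisphere

    def subset(self, channel_ids: Iterable[str]) -> "Montage":
        keep = set(channel_ids)
        return Montage([c for c in self.channels if c.id in keep])

    def mirrored(self) -> "Montage":
        """Montage with all x-coordinates negated (left <-> right)."""

        def flip(p):
            return (-p[0], p[1], p[2])

        def flip_region(r):
            return {"left-temporal": "right-temporal", "right-temporal": "left-temporal"}.get(r, r)

        return Montage(
            [
                ChannelDef(c.id, flip(c.source_pos), flip(c.detector_pos), c.kind, flip_region(c.region))
                for c in self.channels
            ]
        )

    # -- serialization (JSON sidecar) ------------------------------------
    def to_json(self, path) -> None:
        payload = [
            {
                "id": c.id,
                "source_pos": list(c.source_pos),
                "detector_pos": list(c.detector_pos),
                "kind": c.kind,
                "region": c.region,
            }
            for c in self.channels
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Montage":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            [
                ChannelDef(
                    d["id"], tuple(d["source_pos"]), tuple(d["detector_pos"]), d["kind"], d["region"]
                )
                for d in payload
            ]
        )


def default_montage() -> Montage:
    """Build the default 16-source / 16-detector montage.

    Frontal and occipital optodes form 7-optode chains across the midline
    (30 mm spacing, alternating source/detector); each temporal side is a
    5-optode chain.  Eight short channels (11 mm) are formed by dedicated
    optodes next to chain optodes: three frontal, three occipital and one on
    each temporal side.  The layout is mirror-symmetric about the x = 0
    plane.  This yields 20 long channels (10 per hemisphere) and 8 short
    channels from exactly 16 sources and 16 detectors.
    """
    mm = 1e-3
    channels: list[ChannelDef] = []
    src_idx = 0
    det_idx = 0
    sources: dict[str, tuple] = {}
    detectors: dict[str, tuple] = {}

    def new_source(pos):
        nonlocal src_idx
        src_idx += 1
        name = f"S{src_idx}"
        sources[name] = pos
        return name

    def new_detector(pos):
        nonlocal det_idx
        det_idx += 1
        name = f"D{det_idx}"
        detectors[name] = pos
        return name

    def add_channel(s_name, d_name, kind, region):
        channels.append(
            ChannelDef(f"{s_name}-{d_name}", sources[s_name], detectors[d_name], kind, region)
        )

    def build_chain(xy_positions, first_kind, region):
        """Alternating optode chain; adjacent optodes form long channels."""
        names = []
        kinds = []
        k = first_kind
        for pos in xy_positions:
            if k == "S":
                names.append(new_source(pos))
            else:
                names.append(new_detector(pos))
            kinds.append(k)
            k = "D" if k == "S" else "S"
        for a, b, ka in zip(names, names[1:], kinds):
            s, d = (a, b) if ka == "S" else (b, a)
            add_channel(s, d, "long", region)
        return names, kinds

    # frontal chain along x at y = +90 mm: D S D S D S D
    fx = [(-90 + 30 * i) * mm for i in range(7)]
    f_names, f_kinds = build_chain([(x, 0.090, 0.0) for x in fx], "D", "frontal")
    # frontal short channels: short detectors 11 mm anterior of the sources
    for name, kind, x in zip(f_names, f_kinds, fx):
        if kind == "S" :
            d = new_detector((x, 0.090 + 11 * mm, 0.0))
            add_channel(name, d, "short", "frontal")

    # occipital chain along x at y = -90 mm: S D S D S D S
    o_names, o_kinds = build_chain([(x, -0.090, 0.0) for x in fx], "S", "occipital")
    # occipital short channels: short sources 11 mm posterior of the detectors
    for name, kind, x in zip(o_names, o_kinds, fx):
        if kind == "D":
            s = new_source((x, -0.090 - 11 * mm, 0.0))
            add_channel(s, name, "short", "occipital")

    # temporal chains along y at x = -/+70 mm: S D S D S
    ty = [(-60 + 30 * i) * mm for i in range(5)]
    for sign, region in ((-1, "left-temporal"), (+1, "right-temporal")):
        names, kinds = build_chain([(sign * 0.070, y, 0.0) for y in ty], "S", region)
        # one short channel per side, next to the middle source (y = 0)
        mid = names[2]
        d = new_detector((sign * 0.070, 11 * mm, 0.0))
        add_channel(mid, d, "short", region)

    m = Montage(channels)
    assert src_idx == 16 and det_idx == 16, (src_idx, det_idx)
    return m
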