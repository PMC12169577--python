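"""Read and write recordings as SNIRF (HDF5) files.

SNIRF is the community standard container for fNIRS data.  The writer emits
the standard layout (``/formatVersion``, ``/nirs/data1`` with one
measurementList entry per series, ``/nirs/probe`` with 3-D optode positions,
``/nirs/stim*`` blocks) so files are readable by generic SNIRF tools; the
processing stage is encoded in the standard dataType/dataTypeLabel fields
(CW amplitude for raw intensity, ``dOD``/``HbO``/``HbR`` for processed
series), with package-specific sidecar metadata stored under
``metaDataTags``.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .montage import ChannelDef, Montage
from .recording import Event, EventSchedule, Recording, SubjectMeta

_CW_AMPLITUDE = 1
_PROCESSED = 99999

_STAGE_FROM_LABEL = {"dOD": "optical_density", "HbO": "haemoglobin", "HbR": "haemoglobin"}


class SnirfFormatError(ValueError):
    """Raised when a file does not conform to the expected SNIRF layout."""


def _require(group, name):
    if name not in group:
        raise SnirfFormatError(f"malformed SNIRF file: missing '{group.name}/{name}'")
    return group[name]


def _str(value) -> str:
    if isinstance(value, bytes):
        return value.decode()
    if isinstance(value, np.ndarray):
        return _str(value.item() if value.shape == () else value[0])
    return str(value)


def write_snirf(recording: Recording, path, montage: Montage) -> str:
    """Write ``recording`` (+ geometry from ``montage``) to ``path``.

    Returns the path written.  Every series must belong to a channel present
    in the montage.
    """
    missing = [c for c in recording.unique_channels if c not in montage]
    if missing:
        raise ValueError(f"channels absent from montage: {missing}")

    src_names: list[str] = []
    det_names: list[str] = []
    positions: dict[str, tuple] = {}
    for ch in montage.channels:
        s, d = ch.id.split("-")
        if s not in src_names:
            src_names.append(s)
            positions[s] = ch.source_pos
        if d not in det_names:
            det_names.append(d)
            positions[d] = ch.detector_pos

    str_t = h5py.string_dtype()
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0", dtype=str_t)
        nirs = f.create_group("nirs")

        tags = nirs.create_group("metaDataTags")
        meta = recording.meta

        def tag(name, value):
            tags.create_dataset(name, data=value, dtype=str_t)

        tag("SubjectID", meta.subject_id if meta else "unknown")
        tag("MeasurementDate", "unknown")
        tag("MeasurementTime", "unknown")
        tag("LengthUnit", "m")
        tag("TimeUnit", "s")
        tag("FrequencyUnit", "Hz")
        tag("nirslatStage", recording.stage)
        tag("nirslatFs", repr(float(recording.fs)))
        tag("nirslatRunType", recording.run_type)
        tag(
            "nirslatMontage",
            json.dumps(
                {c.id: {"kind": c.kind, "region": c.region} for c in montage.channels}
            ),
        )
        if meta is not None:
            tag("nirslatSubjectMeta", json.dumps(vars(meta)))

        data1 = nirs.create_group("data1")
        data1.create_dataset("dataTimeSeries", data=recording.data, dtype="f8")
        data1.create_dataset("time", data=recording.times, dtype="f8")
        for j, (cid, band) in enumerate(zip(recording.channel_ids, recording.bands)):
            s, d = cid.split("-")
            ml = data1.create_group(f"measurementList{j + 1}")
            ml.create_dataset("sourceIndex", data=src_names.index(s) + 1, dtype="i4")
            ml.create_dataset("detectorIndex", data=det_names.index(d) + 1, dtype="i4")
            if recording.stage == "intensity":
                ml.create_dataset("dataType", data=_CW_AMPLITUDE, dtype="i4")
                ml.create_dataset("wavelengthIndex", data=1 if band == "760" else 2, dtype="i4")
            else:
                ml.create_dataset("dataType", data=_PROCESSED, dtype="i4")
                label = "dOD" if recording.stage == "optical_density" else band
                ml.create_dataset("dataTypeLabel", data=label, dtype=str_t)
                wl = (1 if band == "760" else 2) if recording.stage == "optical_density" else 1
                ml.create_dataset("wavelengthIndex", data=wl, dtype="i4")
            ml.create_dataset("dataTypeIndex", data=1, dtype="i4")

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array([760.0, 850.0]), dtype="f8")
        probe.create_dataset(
            "sourcePos3D", data=np.array([positions[n] for n in src_names]), dtype="f8"
        )
        probe.create_dataset(
            "detectorPos3D", data=np.array([positions[n] for n in det_names]), dtype="f8"
        )
        probe.create_dataset("sourceLabels", data=src_names, dtype=str_t)
        probe.create_dataset("detectorLabels", data=det_names, dtype=str_t)

        for k, cond in enumerate(recording.events.conditions):
            stim = nirs.create_group(f"stim{k + 1}")
            stim.create_dataset("name", data=cond, dtype=str_t)
            rows = [
                [e.onset_s, e.duration_s, 1.0] for e in recording.events.for_condition(cond)
            ]
            stim.create_dataset("data", data=np.array(rows, dtype=float), dtype="f8")
    return str(path)


def read_snirf(path) -> Recording:
    """Read a SNIRF file into a :class:`Recording`.

    The processing stage is inferred from the measurementList data-type
    codes; stimulus blocks populate the event schedule.
    """
    with h5py.File(path, "r") as f:
        nirs = _require(f, "nirs")
        data1 = _require(nirs, "data1")
        series = np.asarray(_require(data1, "dataTimeSeries"))
        time = np.asarray(_require(data1, "time"))
        if time.size < 2:
            raise SnirfFormatError("time axis must have at least 2 samples")
        if time.size == 2 and series.shape[0] != 2:
            fs = 1.0 / float(time[1])  # [start, dt] form
        else:
            dt = np.diff(time)
            if np.ptp(dt) > 1e-6 * dt.mean():
                raise SnirfFormatError("non-uniform time axis")
            fs = 1.0 / float(dt.mean())

        probe = _require(nirs, "probe")
        src_labels = [_str(s) for s in _require(probe, "sourceLabels")[()]]
        det_labels = [_str(s) for s in _require(probe, "detectorLabels")[()]]
        wavelengths = np.asarray(_require(probe, "wavelengths"))

        n_series = series.shape[1]
        channel_ids: list[str] = []
        bands: list[str] = []
        stages = set()
        for j in range(n_series):
            ml = _require(data1, f"measurementList{j + 1}")
            si = int(np.asarray(_require(ml, "sourceIndex")))
            di = int(np.asarray(_require(ml, "detectorIndex")))
            channel_ids.append(f"{src_labels[si - 1]}-{det_labels[di - 1]}")
            dtype_code = int(np.asarray(_require(ml, "dataType")))
            if dtype_code == _CW_AMPLITUDE:
                wl = int(np.asarray(_require(ml, "wavelengthIndex")))
                bands.append(str(int(round(float(wavelengths[wl - 1])))))
                stages.add("intensity")
            elif dtype_code == _PROCESSED:
                label = _str(np.asarray(_require(ml, "dataTypeLabel"))[()])
                if label not in _STAGE_FROM_LABEL:
                    raise SnirfFormatError(f"unsupported dataTypeLabel {label!r}")
                if label == "dOD":
                    wl = int(np.asarray(_require(ml, "wavelengthIndex")))
                    bands.append(str(int(round(float(wavelengths[wl - 1])))))
                else:
                    bands.append(label)
                stages.add(_STAGE_FROM_LABEL[label])
            else:
                raise SnirfFormatError(f"unsupported dataType code {dtype_code}")
        if len(stages) != 1:
            raise SnirfFormatError(f"mixed processing stages in one data block: {sorted(stages)}")
        stage = stages.pop()

        tags = nirs.get("metaDataTags")
        run_type = "rest"
        meta = None
        if tags is not None:
            if "nirslatFs" in tags:
                fs = float(_str(tags["nirslatFs"][()]))
            if "nirslatStage" in tags:
                declared = _str(tags["nirslatStage"][()])
                if declared == "residual" and stage == "haemoglobin":
                    stage = "residual"
            if "nirslatRunType" in tags:
                run_type = _str(tags["nirslatRunType"][()])
            if "nirslatSubjectMeta" in tags:
                meta = SubjectMeta(**json.loads(_str(tags["nirslatSubjectMeta"][()])))

        events = []
        for key in sorted(k for k in nirs if k.startswith("stim")):
            stim = nirs[key]
            name = _str(_require(stim, "name")[()])
            rows = np.atleast_2d(np.asarray(_require(stim, "data")))
            for row in rows:
                if row.size:
                    events.append(Event(float(row[0]), float(row[1]), name))

        return Recording(
            data=series,
            fs=fs,
            stage=stage,
            channel_ids=channel_ids,
            bands=bands,
            events=EventSchedule(events),
            meta=meta,
            run_type=run_type,
        )


def read_snirf_montage(path) -> Montage:
    """Reconstruct the montage (geometry + kind/region labels) from a file."""
    with h5py.File(path, "r") as f:
        nirs = _require(f, "nirs")
        probe = _require(nirs, "probe")
        src_labels = [_str(s) for s in _require(probe, "sourceLabels")[()]]
        det_labels = [_str(s) for s in _require(probe, "detectorLabels")[()]]
        src_pos = np.asarray(_require(probe, "sourcePos3D"))
        det_pos = np.asarray(_require(probe, "detectorPos3D"))
        tags = nirs.get("metaDataTags")
        if tags is None or "nirslatMontage" not in tags:
            raise SnirfFormatError("malformed SNIRF file: missing 'metaDataTags/nirslatMontage'")
        info = json.loads(_str(tags["nirslatMontage"][()]))
        channels = []
        for cid, d in info.items():
            s_name, d_name = cid.split("-")
            channels.append(
                ChannelDef(
                    cid,
                    tuple(src_pos[src_labels.index(s_name)]),
                    tuple(det_pos[det_labels.index(d_name)]),
                    d["kind"],
                    d["region"],
                )
            )
        return Montage(channels)
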