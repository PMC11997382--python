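"""Minimal SNIRF (HDF5) reader/writer plus CSV side-car formats.

Only the subset of the SNIRF layout this pipeline needs is produced: raw
continuous-wave intensity (dataType 1), the probe wavelengths, opaque
source/detector labels and the task/rest stimulus blocks. The measurement
column order is channel-major, wavelength-minor.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .montage import ParadigmSchedule, ScheduleEvent
from .recording import HbRecording, RawRecording
from .simulate import CohortSubject

_STR = h5py.string_dtype(encoding="utf-8")


def write_snirf(path, recording: RawRecording) -> None:
    path = Path(path)
    n_ch = len(recording.channel_ids)
    n_wl = len(recording.wavelengths_nm)
    n_t = recording.n_times
    data = recording.intensity.reshape(n_ch * n_wl, n_t).T  # (time, measurement)

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0", dtype=_STR)
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=recording.subject_id, dtype=_STR)
        meta.create_dataset("MeasurementDate", data="unknown", dtype=_STR)
        meta.create_dataset("MeasurementTime", data="unknown", dtype=_STR)
        meta.create_dataset("LengthUnit", data="cm", dtype=_STR)
        meta.create_dataset("TimeUnit", data="s", dtype=_STR)
        meta.create_dataset("FrequencyUnit", data="Hz", dtype=_STR)

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(recording.wavelengths_nm, float))
        probe.create_dataset(
            "sourceLabels",
            data=np.asarray([f"S{c}" for c in recording.channel_ids], dtype=object),
            dtype=_STR,
        )
        probe.create_dataset(
            "detectorLabels",
            data=np.asarray([f"D{c}" for c in recording.channel_ids], dtype=object),
            dtype=_STR,
        )

        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset(
            "time", data=np.arange(n_t) / recording.sampling_rate_hz
        )
        m = 1
        for ci, cid in enumerate(recording.channel_ids):
            for wi in range(n_wl):
                ml = d1.create_group(f"measurementList{m}")
                ml.create_dataset("sourceIndex", data=ci + 1, dtype="i4")
                ml.create_dataset("detectorIndex", data=ci + 1, dtype="i4")
                ml.create_dataset("wavelengthIndex", data=wi + 1, dtype="i4")
                ml.create_dataset("dataType", data=1, dtype="i4")
                ml.create_dataset("dataTypeIndex", data=1, dtype="i4")
                ml.create_dataset("channelId", data=int(cid), dtype="i4")
                m += 1

        if recording.schedule is not None:
            for si, condition in enumerate(("task", "rest"), start=1):
                events = [
                    ev for ev in recording.schedule.events if ev.condition == condition
                ]
                stim = nirs.create_group(f"stim{si}")
                stim.create_dataset("name", data=condition, dtype=_STR)
                stim.create_dataset(
                    "data",
                    data=np.asarray(
                        [[ev.onset_s, ev.duration_s, 1.0] for ev in events], float
                    ),
                )


def _schedule_from_stims(stims: dict[str, np.ndarray], total_duration_s: float
                         ) -> ParadigmSchedule | None:
    if "task" not in stims:
        return None
    events: list[ScheduleEvent] = []
    for condition, data in stims.items():
        for onset, duration, _ in np.atleast_2d(data):
            events.append(ScheduleEvent(condition, float(onset), float(duration)))
    events.sort(key=lambda e: e.onset_s)
    pre = events[0].onset_s
    post = total_duration_s - (events[-1].onset_s + events[-1].duration_s)
    return ParadigmSchedule(
        events=tuple(events),
        pre_baseline_s=pre,
        post_baseline_s=max(post, 0.0),
        total_duration_s=total_duration_s,
    )


def read_snirf(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        d1 = nirs["data1"]
        data = np.asarray(d1["dataTimeSeries"])
        time = np.asarray(d1["time"])
        if len(time) < 2:
            raise InvalidParameterError("time vector too short")
        fs = 1.0 / float(np.median(np.diff(time)))
        wavelengths = tuple(float(w) for w in np.asarray(nirs["probe"]["wavelengths"]))
        n_wl = len(wavelengths)

        ml_names = sorted(
            (k for k in d1.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        if len(ml_names) != data.shape[1]:
            raise InvalidParameterError("measurement list does not match data columns")
        channel_ids: list[int] = []
        for k in ml_names:
            ml = d1[k]
            wl_idx = int(np.asarray(ml["wavelengthIndex"]))
            if "channelId" in ml:
                cid = int(np.asarray(ml["channelId"]))
            else:
                cid = int(np.asarray(ml["sourceIndex"]))
            if wl_idx == 1:
                channel_ids.append(cid)
        n_ch = len(channel_ids)
        intensity = data.T.reshape(n_ch, n_wl, -1)

        subject_id = "unknown"
        if "metaDataTags" in nirs and "SubjectID" in nirs["metaDataTags"]:
            raw = nirs["metaDataTags"]["SubjectID"][()]
            subject_id = raw.decode() if isinstance(raw, bytes) else str(raw)

        stims = {}
        for k in nirs.keys():
            if k.startswith("stim"):
                raw = nirs[k]["name"][()]
                name = raw.decode() if isinstance(raw, bytes) else str(raw)
                stims[name] = np.asarray(nirs[k]["data"])
        total = len(time) / fs
        schedule = _schedule_from_stims(stims, total)

    return RawRecording(
        subject_id=subject_id,
        intensity=intensity,
        channel_ids=tuple(channel_ids),
        wavelengths_nm=wavelengths,
        sampling_rate_hz=fs,
        schedule=schedule,
    )


def hb_to_csv(hb: HbRecording, path) -> None:
    """Long-format export: subject, channel, chromophore, time_s, value."""
    n_t = hb.n_times
    times = np.arange(n_t) / hb.sampling_rate_hz
    frames = []
    for i, cid in enumerate(hb.channel_ids):
        for k, chrom in enumerate(hb.chromophores):
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": hb.subject_id,
                        "channel_id": cid,
                        "chromophore": chrom,
                        "time_s": times,
                        "value_umol_per_l": hb.conc_um[i, k],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_cohort(out_dir, cohort: list[CohortSubject]) -> None:
    """One SNIRF file per subject plus metadata CSV and ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    truth = {}
    for subj in cohort:
        write_snirf(out / f"{subj.profile.subject_id}.snirf", subj.recording)
        meta_rows.append(
            {
                "subject_id": subj.profile.subject_id,
                "diagnosis": subj.profile.diagnosis,
                "gose_6mo": subj.profile.gose_6mo if subj.profile.gose_6mo is not None else "",
            }
        )
        truth[subj.profile.subject_id] = {
            "responder": subj.truth.responder,
            "artifact_indices": list(subj.truth.artifact_indices),
            "bad_channel_ids": sorted(subj.truth.bad_channel_ids),
        }
    pd.DataFrame(meta_rows).to_csv(out / "metadata.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
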