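"""Acquisition constants and the timed block paradigm.

The montage (63 channels, 3 wavelengths, 11 Hz, 3 cm source-detector
separation), the 10-region channel map and the 300 s block schedule are the
single source of truth that every downstream stage (simulation, epoching,
feature windows) indexes against.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import NamedTuple

from .errors import InvalidParadigmError

N_CHANNELS = 63
SOURCE_DETECTOR_DISTANCE_CM = 3.0
WAVELENGTHS_NM = (703.0, 808.0, 850.0)
SAMPLING_RATE_HZ = 11.0

#: Channel membership of the ten cortical regions.
ROI_CHANNELS: dict[str, frozenset[int]] = {
    "LPFC": frozenset({8, 9, 10, 11, 12, 23, 24, 25, 26, 29, 39}),
    "RPFC": frozenset({3, 4, 5, 6, 7, 18, 19, 20, 22, 34, 35}),
    "LPMC": frozenset({27, 36, 37, 38, 40, 41}),
    "RPMC": frozenset({31, 33, 46, 47, 50, 51}),
    "LM1": frozenset({54, 55, 57}),
    "RM1": frozenset({30, 32, 45}),
    "LPC": frozenset({13, 14, 15, 52, 53, 56}),
    "RPC": frozenset({1, 2, 16, 17, 44, 48}),
    "LOC": frozenset({60, 61, 62, 63}),
    "ROC": frozenset({42, 43, 58, 59}),
}

#: Motor-related regions that carry the imagery response and feed the classifier.
MOTOR_ROIS = ("LPMC", "RPMC", "LM1", "RM1")

#: Channels that belong to no region; carried through preprocessing but never
#: entering any regional average.
UNASSIGNED_CHANNELS = frozenset({21, 28, 49})


@dataclass(frozen=True)
class Channel:
    """One source-detector measurement channel.

    Source/detector labels are opaque identifiers: the acquisition geometry
    (which optode pairs form which channel) is not modelled, only the fixed
    3 cm separation.
    """

    channel_id: int
    source: str
    detector: str
    distance_cm: float = SOURCE_DETECTOR_DISTANCE_CM


@dataclass(frozen=True)
class Montage:
    channels: tuple[Channel, ...]
    wavelengths_nm: tuple[float, ...] = WAVELENGTHS_NM
    sampling_rate_hz: float = SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        if len(self.channels) != N_CHANNELS:
            raise InvalidParadigmError(
                f"montage must have {N_CHANNELS} channels, got {len(self.channels)}"
            )
        ids = [ch.channel_id for ch in self.channels]
        if ids != list(range(1, N_CHANNELS + 1)):
            raise InvalidParadigmError("channel ids must be 1..63 in order")
        if any(ch.distance_cm != SOURCE_DETECTOR_DISTANCE_CM for ch in self.channels):
            raise InvalidParadigmError("all source-detector distances must be 3.0 cm")
        if list(self.wavelengths_nm) != sorted(self.wavelengths_nm):
            raise InvalidParadigmError("wavelengths must be strictly increasing")
        if self.sampling_rate_hz <= 0:
            raise InvalidParadigmError("sampling rate must be positive")

    @property
    def channel_ids(self) -> tuple[int, ...]:
        return tuple(ch.channel_id for ch in self.channels)

    def to_json(self) -> str:
        payload = {
            "sampling_rate_hz": self.sampling_rate_hz,
            "wavelengths_nm": list(self.wavelengths_nm),
            "channels": [
                {
                    "channel_id": ch.channel_id,
                    "source": ch.source,
                    "detector": ch.detector,
                    "distance_cm": ch.distance_cm,
                }
                for ch in self.channels
            ],
        }
        return json.dumps(payload, indent=2)


class ScheduleEvent(NamedTuple):
    condition: str  # "task" | "rest"
    onset_s: float
    duration_s: float


@dataclass(frozen=True)
class ParadigmSchedule:
    """Ordered task/rest events framed by pre- and post-baseline periods."""

    events: tuple[ScheduleEvent, ...]
    pre_baseline_s: float
    post_baseline_s: float
    total_duration_s: float

    @property
    def task_onsets(self) -> tuple[float, ...]:
        return tuple(e.onset_s for e in self.events if e.condition == "task")

    @property
    def rest_onsets(self) -> tuple[float, ...]:
        return tuple(e.onset_s for e in self.events if e.condition == "rest")

    @property
    def n_blocks(self) -> int:
        return len(self.task_onsets)

    def n_samples(self, sampling_rate_hz: float) -> int:
        return int(round(self.total_duration_s * sampling_rate_hz))

    def to_tsv(self) -> str:
        lines = ["condition\tonset_s\tduration_s"]
        for ev in self.events:
            lines.append(f"{ev.condition}\t{ev.onset_s:g}\t{ev.duration_s:g}")
        return "\n".join(lines) + "\n"


def sample_index(onset_s: float, sampling_rate_hz: float) -> int:
    """Convert an event time to a sample index by rounding.

    At 11 Hz most onsets fall between samples, so the convention
    ``round(onset * rate)`` is fixed here and used by every consumer.
    """
    return int(round(onset_s * sampling_rate_hz))


def build_montage() -> Montage:
    """Return the fixed 63-channel, 3-wavelength acquisition montage."""
    channels = tuple(
        Channel(
            channel_id=i,
            source=f"S{(i - 1) // 3 + 1}",
            detector=f"D{(i - 1) % 24 + 1}",
        )
        for i in range(1, N_CHANNELS + 1)
    )
    return Montage(channels=channels)


def build_roi_map() -> dict[str, frozenset[int]]:
    """Return the 10-region channel map (a fresh copy of the constant)."""
    return dict(ROI_CHANNELS)


def roi_map_to_json(roi_map: dict[str, frozenset[int]] | None = None) -> str:
    roi_map = ROI_CHANNELS if roi_map is None else roi_map
    return json.dumps({k: sorted(v) for k, v in roi_map.items()}, indent=2)


def roi_map_from_json(payload: str) -> dict[str, frozenset[int]]:
    raw = json.loads(payload)
    return {k: frozenset(v) for k, v in raw.items()}


def build_schedule(
    pre_baseline_s: float = 50.0,
    n_blocks: int = 5,
    task_s: float = 20.0,
    rest_s: float = 20.0,
    post_baseline_s: float = 50.0,
) -> ParadigmSchedule:
    """Build the alternating task/rest block schedule.

    With defaults: 50 s baseline, five (20 s task + 20 s rest) blocks, 50 s
    post-baseline, 300 s total. The rest command of block *k* starts exactly
    when its task period ends.
    """
    if n_blocks < 1 or task_s <= 0 or rest_s <= 0:
        raise InvalidParadigmError("n_blocks, task_s and rest_s must be positive")
    if pre_baseline_s < 0 or post_baseline_s < 0:
        raise InvalidParadigmError("baseline durations must be non-negative")
    events: list[ScheduleEvent] = []
    t = float(pre_baseline_s)
    for _ in range(n_blocks):
        events.append(ScheduleEvent("task", t, float(task_s)))
        t += task_s
        events.append(ScheduleEvent("rest", t, float(rest_s)))
        t += rest_s
    total = t + post_baseline_s
    return ParadigmSchedule(
        events=tuple(events),
        pre_baseline_s=float(pre_baseline_s),
        post_baseline_s=float(post_baseline_s),
        total_duration_s=float(total),
    )


def motor_channel_ids(roi_map: dict[str, frozenset[int]] | None = None) -> frozenset[int]:
    roi_map = ROI_CHANNELS if roi_map is None else roi_map
    out: set[int] = set()
    for roi in MOTOR_ROIS:
        out |= roi_map[roi]
    return frozenset(out)
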