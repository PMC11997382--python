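"""Array containers for the three signal states of the processing chain."""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidIntensityError, InvalidParameterError
from .montage import ParadigmSchedule
from .optics import CHROMOPHORES


@dataclass
class RawRecording:
    """Raw light intensity, shape (n_channels, n_wavelengths, n_times)."""

    subject_id: str
    intensity: np.ndarray
    channel_ids: tuple[int, ...]
    wavelengths_nm: tuple[float, ...]
    sampling_rate_hz: float
    schedule: ParadigmSchedule | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise InvalidParameterError("intensity must be (channels, wavelengths, time)")
        n_ch, n_wl, _ = self.intensity.shape
        if n_ch != len(self.channel_ids) or n_wl != len(self.wavelengths_nm):
            raise InvalidParameterError("intensity shape does not match channel/wavelength lists")
        if not np.all(np.isfinite(self.intensity)):
            raise InvalidIntensityError("intensities must be finite")
        if np.any(self.intensity <= 0):
            raise InvalidIntensityError("intensities must be strictly positive")

    @property
    def n_times(self) -> int:
        return self.intensity.shape[2]

    def channel_index(self, channel_id: int) -> int:
        return self.channel_ids.index(channel_id)

    def restrict(self, keep_ids) -> "RawRecording":
        keep = [i for i, cid in enumerate(self.channel_ids) if cid in set(keep_ids)]
        return replace(
            self,
            intensity=self.intensity[keep],
            channel_ids=tuple(self.channel_ids[i] for i in keep),
        )


@dataclass
class ODRecording:
    """Optical density changes, shape (n_channels, n_wavelengths, n_times)."""

    subject_id: str
    od: np.ndarray
    channel_ids: tuple[int, ...]
    wavelengths_nm: tuple[float, ...]
    sampling_rate_hz: float
    schedule: ParadigmSchedule | None = None

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 3:
            raise InvalidParameterError("od must be (channels, wavelengths, time)")
        if not np.all(np.isfinite(self.od)):
            raise InvalidParameterError("optical density must be finite")

    @property
    def n_times(self) -> int:
        return self.od.shape[2]


@dataclass
class HbRecording:
    """Concentration changes in µmol/L, shape (n_channels, 2, n_times).

    Chromophore axis order is fixed: ("hbo", "hbr").
    """

    subject_id: str
    conc_um: np.ndarray
    channel_ids: tuple[int, ...]
    sampling_rate_hz: float
    schedule: ParadigmSchedule | None = None
    chromophores: tuple[str, ...] = CHROMOPHORES

    def __post_init__(self) -> None:
        self.conc_um = np.asarray(self.conc_um, dtype=float)
        if self.conc_um.ndim != 3 or self.conc_um.shape[1] != len(self.chromophores):
            raise InvalidParameterError("conc_um must be (channels, chromophores, time)")
        if not np.all(np.isfinite(self.conc_um)):
            raise InvalidParameterError("concentrations must be finite")

    @property
    def n_times(self) -> int:
        return self.conc_um.shape[2]

    def channel_index(self, channel_id: int) -> int:
        return self.channel_ids.index(channel_id)

    def series(self, channel_id: int, chromophore: str) -> np.ndarray:
        return self.conc_um[self.channel_index(channel_id), self.chromophores.index(chromophore)]
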