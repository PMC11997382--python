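"""Signal chain: CV channel screen -> optical density -> motion correction
-> band-pass -> Beer-Lambert concentration solve.

Interpretation choices that the originating method leaves open are fixed and
documented here:

* The coefficient of variation uses the sample (n-1) standard deviation over
  the whole raw intensity series, per channel per wavelength; a channel is
  dropped when ANY wavelength exceeds the threshold (strict inequality).
* Optical density is referenced to the temporal mean of each series.
* Motion flagging combines a moving-SD rule (moving SD > multiplier x median
  moving SD of the same series, a robust per-series scale) with an absolute
  sample-to-sample amplitude rule in OD units. Flagged runs are corrected by
  subtracting a smoothing spline fitted within the run, re-levelling the run
  to the preceding clean data, and shifting the subsequent samples to keep
  the record continuous.
* The band-pass is a 3rd-order Butterworth applied forward-backward.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline
from scipy.ndimage import binary_dilation, uniform_filter1d
from scipy.signal import butter, sosfiltfilt

from .errors import (
    AllChannelsRejectedError,
    InvalidFilterError,
    InvalidIntensityError,
    InvalidParameterError,
    UndefinedCVError,
)
from .optics import od_to_concentrations
from .recording import HbRecording, ODRecording, RawRecording


def coefficient_of_variation(series) -> float:
    """(sample SD / mean) x 100, in percent."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise UndefinedCVError("empty series")
    mean = x.mean()
    if mean == 0:
        raise UndefinedCVError("zero-mean series has undefined CV")
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    return float(sd / mean * 100.0)


def reject_channels(
    recording: RawRecording, threshold: float = 15.0
) -> tuple[RawRecording, pd.DataFrame]:
    """Drop channels whose raw-intensity CV exceeds ``threshold`` percent at
    any wavelength. Returns the restricted recording and a per-channel,
    per-wavelength QC report."""
    rows = []
    rejected_ids: set[int] = set()
    for i, cid in enumerate(recording.channel_ids):
        for w, wl in enumerate(recording.wavelengths_nm):
            cv = coefficient_of_variation(recording.intensity[i, w])
            bad = cv > threshold
            rows.append(
                {
                    "channel_id": cid,
                    "wavelength_nm": wl,
                    "cv_percent": cv,
                    "rejected": bad,
                    "reason": f"CV {cv:.1f}% > {threshold:g}%" if bad else "",
                }
            )
            if bad:
                rejected_ids.add(cid)
    report = pd.DataFrame(rows)
    # a channel is rejected as a whole if any wavelength failed
    report["rejected"] = report["channel_id"].isin(rejected_ids)
    retained = [cid for cid in recording.channel_ids if cid not in rejected_ids]
    if not retained:
        raise AllChannelsRejectedError(
            f"all {len(recording.channel_ids)} channels exceeded CV {threshold:g}%"
        )
    return recording.restrict(retained), report


def to_optical_density(recording: RawRecording) -> ODRecording:
    """OD(t) = -log10(I(t) / mean_t I) per channel per wavelength."""
    if np.any(recording.intensity <= 0):
        raise InvalidIntensityError("intensities must be strictly positive")
    ref = recording.intensity.mean(axis=2, keepdims=True)
    od = -np.log10(recording.intensity / ref)
    return ODRecording(
        subject_id=recording.subject_id,
        od=od,
        channel_ids=recording.channel_ids,
        wavelengths_nm=recording.wavelengths_nm,
        sampling_rate_hz=recording.sampling_rate_hz,
        schedule=recording.schedule,
    )


@dataclass(frozen=True)
class ArtifactSegment:
    channel_id: int
    wavelength_nm: float
    start: int
    stop: int  # half-open sample range


def _moving_sd(y: np.ndarray, w: int) -> np.ndarray:
    m = uniform_filter1d(y, size=w, mode="nearest")
    m2 = uniform_filter1d(y * y, size=w, mode="nearest")
    var = np.maximum(m2 - m * m, 0.0)
    return np.sqrt(var)


def _flag_samples(y: np.ndarray, w: int, sd_threshold: float, amp_threshold: float) -> np.ndarray:
    msd = _moving_sd(y, w)
    med = float(np.median(msd))
    # absolute floor keeps numerical dust on near-flat series from flagging
    floor = 1e-9 * max(1.0, float(np.ptp(y)))
    flags = msd > max(sd_threshold * med, floor)
    d = np.abs(np.diff(y))
    jump = d > amp_threshold
    flags[:-1] |= jump
    flags[1:] |= jump
    if flags.any():
        flags = binary_dilation(flags, structure=np.ones(2 * (w // 2) + 1, dtype=bool))
    return flags


def _segments(flags: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    return [(int(g[0]), int(g[-1]) + 1) for g in np.split(idx, splits)]


def _noise_sigma(y: np.ndarray, flags: np.ndarray) -> float:
    d = np.diff(y)
    keep = ~(flags[:-1] | flags[1:])
    d = d[keep]
    if d.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d)) / np.sqrt(2.0))


def _correct_series(
    y: np.ndarray, w: int, sd_threshold: float, amp_threshold: float
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    flags = _flag_samples(y, w, sd_threshold, amp_threshold)
    segs = _segments(flags)
    if not segs:
        return y.copy(), []
    out = y.copy()
    sigma = _noise_sigma(y, flags)
    n = len(y)
    for s, e in segs:
        seg = out[s:e].copy()
        if e - s >= 4:
            t = np.arange(s, e, dtype=float)
            spl = UnivariateSpline(t, seg, k=3, s=(e - s) * sigma**2)
            trend = spl(t)
        else:
            trend = seg
        resid = seg - trend
        if s > 0:
            base = out[max(0, s - w):s].mean()
        elif e < n:
            base = out[e:min(e + w, n)].mean()
        else:
            base = 0.0
        out[s:e] = base + resid
        if e < n:
            m = min(w, e - s, n - e)
            shift = out[e:e + m].mean() - out[e - m:e].mean()
            out[e:] -= shift
    return out, segs


def correct_motion(
    od: ODRecording,
    window_s: float = 1.0,
    sd_threshold: float = 6.0,
    amp_threshold: float = 0.5,
) -> tuple[ODRecording, list[ArtifactSegment]]:
    """Sliding-window artifact detection with cubic-spline correction.

    Clean input passes through untouched; spikes are flattened toward the
    local level and baseline shifts are re-levelled so that the record stays
    continuous across corrected runs.
    """
    w = int(round(window_s * od.sampling_rate_hz))
    if w < 2:
        raise InvalidParameterError("motion window must span at least 2 samples")
    corrected = od.od.copy()
    found: list[ArtifactSegment] = []
    for i, cid in enumerate(od.channel_ids):
        for k, wl in enumerate(od.wavelengths_nm):
            fixed, segs = _correct_series(od.od[i, k], w, sd_threshold, amp_threshold)
            corrected[i, k] = fixed
            found.extend(ArtifactSegment(cid, wl, s, e) for s, e in segs)
    return replace(od, od=corrected), found


def bandpass(od: ODRecording, low_hz: float = 0.01, high_hz: float = 0.1,
             order: int = 3) -> ODRecording:
    """Zero-phase Butterworth band-pass along the time axis."""
    nyq = od.sampling_rate_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise InvalidFilterError(
            f"need 0 < low < high < Nyquist ({nyq:g} Hz); got [{low_hz}, {high_hz}]"
        )
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=od.sampling_rate_hz,
                 output="sos")
    # Demean before filtering and filter without edge padding: reflection
    # padding leaks edge kinks into the very low passband and produces large,
    # slowly decaying transients. The residual DC (O(1/n) edge effect) is
    # projected out afterwards, consistent with a filter whose DC gain is 0.
    x = od.od - od.od.mean(axis=2, keepdims=True)
    filtered = sosfiltfilt(sos, x, axis=2, padtype=None)
    filtered = filtered - filtered.mean(axis=2, keepdims=True)
    return replace(od, od=filtered)


def mbll(od: ODRecording, dpf: float = 6.0, distance_cm: float = 3.0) -> HbRecording:
    """Least-squares concentration solve over the wavelengths, in µmol/L."""
    conc = od_to_concentrations(od.od, od.wavelengths_nm, dpf=dpf, distance_cm=distance_cm)
    return HbRecording(
        subject_id=od.subject_id,
        conc_um=conc,
        channel_ids=od.channel_ids,
        sampling_rate_hz=od.sampling_rate_hz,
        schedule=od.schedule,
    )


@dataclass(frozen=True)
class MotionConfig:
    window_s: float = 1.0
    sd_threshold: float = 6.0
    amp_threshold: float = 0.5


@dataclass(frozen=True)
class PreprocessConfig:
    cv_threshold: float = 15.0
    motion: MotionConfig | None = field(default_factory=MotionConfig)
    band_hz: tuple[float, float] | None = (0.01, 0.1)
    dpf: float = 6.0
    distance_cm: float = 3.0


def preprocess_chain(
    recording: RawRecording, config: PreprocessConfig = PreprocessConfig()
) -> tuple[HbRecording, pd.DataFrame]:
    """Run the full chain in its fixed order.

    Stages can be disabled through the config (``motion=None``,
    ``band_hz=None``) for diagnostics such as noise-free round-trip checks;
    the order itself is not configurable.
    """
    retained, report = reject_channels(recording, threshold=config.cv_threshold)
    od = to_optical_density(retained)
    if config.motion is not None:
        od, _ = correct_motion(
            od,
            window_s=config.motion.window_s,
            sd_threshold=config.motion.sd_threshold,
            amp_threshold=config.motion.amp_threshold,
        )
    if config.band_hz is not None:
        od = bandpass(od, low_hz=config.band_hz[0], high_hz=config.band_hz[1])
    hb = mbll(od, dpf=config.dpf, distance_cm=config.distance_cm)
    return hb, report
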