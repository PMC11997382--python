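"""Synthetic multi-wavelength recordings with known ground truth.

Virtual cohorts (healthy controls, MCS+, covert responders among the
behaviorally unresponsive groups, and true non-responders) are generated by
planting a canonical hemodynamic response on the motor-region channels of
responders, adding structured physiological noise (cardiac, respiratory,
~0.1 Hz vasomotor waves, low-frequency drift), mapping concentrations to
3-wavelength intensities through the same Beer-Lambert forward model the
preprocessor inverts, and optionally injecting motion artifacts and
high-variability "bad" channels.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

from .errors import InvalidParameterError, ReproducibilityError
from .montage import (
    Montage,
    ParadigmSchedule,
    build_montage,
    build_schedule,
    motor_channel_ids,
    sample_index,
)
from .recording import RawRecording

DIAGNOSES = ("HC", "VS/UWS", "MCS-", "MCS+")

#: Intensity floor (detector units) applied before the log transform; hits are
#: counted so that silent clipping never masks a mis-scaled simulation.
_INTENSITY_FLOOR = 1e-9


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    diagnosis: str
    responder: bool
    hbo_amplitude_um: float = 0.5
    hbr_ratio: float = -0.3
    hbr_lag_s: float = 1.0
    noise_scale: float = 1.0
    artifact_rate_per_min: float = 0.0
    bad_channel_ids: frozenset[int] = frozenset()
    gose_6mo: int | None = None

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise InvalidParameterError(f"unknown diagnosis {self.diagnosis!r}")
        if self.diagnosis == "HC" and not self.responder:
            raise InvalidParameterError("healthy controls are responders by definition")
        if self.hbo_amplitude_um < 0:
            raise InvalidParameterError("hbo_amplitude_um must be >= 0")
        if self.gose_6mo is not None and not 1 <= self.gose_6mo <= 8:
            raise InvalidParameterError("gose_6mo must be in 1..8")


@dataclass
class GroundTruth:
    subject_id: str
    responder: bool
    dhbo_um: np.ndarray  # (n_channels, n_times)
    dhbr_um: np.ndarray
    artifact_indices: tuple[int, ...]
    bad_channel_ids: frozenset[int]
    n_intensity_clamped: int = 0


@dataclass(frozen=True)
class NoiseModel:
    """Additive optical-density noise components (amplitudes at noise_scale 1)."""

    cardiac_hz: float = 1.1
    cardiac_od: float = 0.02
    resp_hz: float = 0.25
    resp_od: float = 0.012
    mayer_hz: float = 0.1
    mayer_od: float = 0.006
    drift_od: float = 0.008
    white_od: float = 0.002


def canonical_hrf(
    t,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
):
    """Double-gamma impulse response, zero at t=0, unit-scale main lobe.

    Gamma densities with unit scale are used, so the main lobe's mode sits at
    ``peak_s`` and the undershoot's at ``undershoot_s``.
    """
    if peak_s <= 0 or undershoot_s <= 0 or undershoot_ratio <= 0:
        raise InvalidParameterError("hrf shape parameters must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("hrf is causal; t must be >= 0")
    main = gamma_dist.pdf(t, a=peak_s + 1.0)
    under = gamma_dist.pdf(t, a=undershoot_s + 1.0)
    return main - undershoot_ratio * under


def task_regressor(schedule: ParadigmSchedule, sampling_rate_hz: float,
                   **hrf_kwargs) -> np.ndarray:
    """Boxcar of task events convolved with the canonical impulse response.

    Normalised to unit peak so that planted amplitudes are exact peak
    concentrations; all zeros if the schedule has no task events.
    """
    n = schedule.n_samples(sampling_rate_hz)
    boxcar = np.zeros(n)
    for ev in schedule.events:
        if ev.condition != "task":
            continue
        a = sample_index(ev.onset_s, sampling_rate_hz)
        b = sample_index(ev.onset_s + ev.duration_s, sampling_rate_hz)
        boxcar[a:b] = 1.0
    dt = 1.0 / sampling_rate_hz
    t_hrf = np.arange(0.0, 32.0, dt)
    kernel = canonical_hrf(t_hrf, **hrf_kwargs)
    reg = np.convolve(boxcar, kernel)[:n] * dt
    peak = reg.max()
    if peak > 0:
        reg = reg / peak
    return reg


def _pink_drift(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance low-frequency drift (demeaned, detrended random walk)."""
    rw = np.cumsum(rng.standard_normal(n))
    t = np.arange(n)
    coef = np.polyfit(t, rw, 1)
    rw = rw - np.polyval(coef, t)
    sd = rw.std()
    return rw / sd if sd > 0 else rw


def simulate_subject(
    profile: SubjectProfile,
    schedule: ParadigmSchedule | None = None,
    montage: Montage | None = None,
    seed: int | None = None,
    noise: NoiseModel = NoiseModel(),
    dpf: float = 6.0,
) -> tuple[RawRecording, GroundTruth]:
    """Generate one subject's raw 3-wavelength intensity recording.

    Responders receive the planted ΔHbO (and lagged, scaled ΔHbR) on the
    motor-region channels only; every channel receives structured noise
    scaled by ``profile.noise_scale``; designated bad channels get enough
    extra white noise to exceed the 15% coefficient-of-variation screen.
    """
    if seed is None:
        raise ReproducibilityError("simulate_subject requires an explicit seed")
    schedule = schedule if schedule is not None else build_schedule()
    montage = montage if montage is not None else build_montage()
    rng = np.random.default_rng(seed)

    fs = montage.sampling_rate_hz
    n_ch = len(montage.channels)
    n_wl = len(montage.wavelengths_nm)
    n = schedule.n_samples(fs)

    # --- planted concentrations -------------------------------------------
    dhbo = np.zeros((n_ch, n))
    dhbr = np.zeros((n_ch, n))
    if profile.responder and profile.hbo_amplitude_um > 0:
        reg = profile.hbo_amplitude_um * task_regressor(schedule, fs)
        lag = sample_index(profile.hbr_lag_s, fs)
        reg_lagged = np.concatenate([np.zeros(lag), reg[: n - lag]]) if lag else reg
        motor = motor_channel_ids()
        for i, ch in enumerate(montage.channels):
            if ch.channel_id in motor:
                dhbo[i] = reg
                dhbr[i] = profile.hbr_ratio * reg_lagged

    from .optics import concentrations_to_od  # local import avoids cycle at module load

    od = concentrations_to_od(
        dhbo, dhbr, montage.wavelengths_nm, dpf=dpf,
        distance_cm=montage.channels[0].distance_cm,
    )  # (n_ch, n_wl, n)

    # --- physiological noise ----------------------------------------------
    t = np.arange(n) / fs
    scale = profile.noise_scale
    if scale > 0:
        for i in range(n_ch):
            for w in range(n_wl):
                series = np.zeros(n)
                for f0, amp in (
                    (noise.cardiac_hz, noise.cardiac_od),
                    (noise.resp_hz, noise.resp_od),
                    (noise.mayer_hz, noise.mayer_od),
                ):
                    f = f0 * (1.0 + 0.02 * rng.standard_normal())
                    a = amp * rng.uniform(0.8, 1.2)
                    series += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
                series += noise.drift_od * _pink_drift(rng, n)
                series += noise.white_od * rng.standard_normal(n)
                od[i, w] += scale * series

    # --- bad channels: inflate variability past the CV screen --------------
    for cid in profile.bad_channel_ids:
        i = montage.channel_ids.index(cid)
        od[i] += 0.15 * rng.standard_normal((n_wl, n))

    # --- motion artifacts: spikes and baseline shifts ----------------------
    artifact_indices: list[int] = []
    if profile.artifact_rate_per_min > 0:
        minutes = schedule.total_duration_s / 60.0
        n_events = rng.poisson(profile.artifact_rate_per_min * minutes)
        for _ in range(n_events):
            idx = int(rng.integers(1, n - 1))
            artifact_indices.append(idx)
            sign = rng.choice([-1.0, 1.0])
            jitter = rng.uniform(0.8, 1.2, size=(n_ch, n_wl))
            if rng.uniform() < 0.5:
                amp = rng.uniform(0.5, 2.0)
                od[:, :, idx] += sign * amp * jitter
            else:
                amp = rng.uniform(0.2, 1.0)
                od[:, :, idx:] += (sign * amp * jitter)[:, :, None]

    # --- map optical density to detector intensities -----------------------
    i0 = rng.uniform(0.5, 2.0, size=(n_ch, n_wl))
    intensity = i0[:, :, None] * np.power(10.0, -od)
    n_clamped = int(np.sum(intensity < _INTENSITY_FLOOR))
    intensity = np.maximum(intensity, _INTENSITY_FLOOR)

    rec = RawRecording(
        subject_id=profile.subject_id,
        intensity=intensity,
        channel_ids=montage.channel_ids,
        wavelengths_nm=montage.wavelengths_nm,
        sampling_rate_hz=fs,
        schedule=schedule,
    )
    truth = GroundTruth(
        subject_id=profile.subject_id,
        responder=profile.responder,
        dhbo_um=dhbo,
        dhbr_um=dhbr,
        artifact_indices=tuple(sorted(artifact_indices)),
        bad_channel_ids=profile.bad_channel_ids,
        n_intensity_clamped=n_clamped,
    )
    return rec, truth


@dataclass
class CohortSubject:
    profile: SubjectProfile
    recording: RawRecording
    truth: GroundTruth


def _draw_gose(rng: np.random.Generator, favorable_p: float) -> int:
    if rng.uniform() < favorable_p:
        return int(rng.integers(4, 9))
    return int(rng.integers(1, 4))


def simulate_cohort(
    n_hc: int,
    n_mcs_plus: int,
    n_vs: int,
    n_mcs_minus: int,
    cmd_fraction: float,
    seed: int | None = None,
    schedule: ParadigmSchedule | None = None,
    montage: Montage | None = None,
    noise: NoiseModel = NoiseModel(),
    profile_kwargs: dict | None = None,
    favorable_p_responder: float = 0.6,
    favorable_p_nonresponder: float = 0.08,
) -> list[CohortSubject]:
    """Simulate a labelled cohort.

    All healthy controls and MCS+ subjects are responders. Within each of the
    behaviorally unresponsive groups (VS/UWS, MCS-), ``round(cmd_fraction *
    n)`` randomly chosen subjects are planted covert responders. Six-month
    outcome scores are drawn with an elevated favorable probability for
    responders. One seed drives everything through independent spawned
    per-subject streams.
    """
    if seed is None:
        raise ReproducibilityError("simulate_cohort requires an explicit seed")
    if min(n_hc, n_mcs_plus, n_vs, n_mcs_minus) < 0:
        raise InvalidParameterError("cohort counts must be non-negative")
    if not 0.0 <= cmd_fraction <= 1.0:
        raise InvalidParameterError("cmd_fraction must be in [0, 1]")
    schedule = schedule if schedule is not None else build_schedule()
    montage = montage if montage is not None else build_montage()
    profile_kwargs = dict(profile_kwargs or {})

    root = np.random.SeedSequence(seed)
    plan_rng = np.random.default_rng(root.spawn(1)[0])

    specs: list[tuple[str, str, bool]] = []
    for k in range(n_hc):
        specs.append((f"HC{k + 1:03d}", "HC", True))
    for k in range(n_mcs_plus):
        specs.append((f"MCSP{k + 1:03d}", "MCS+", True))
    for group, prefix, count in (("VS/UWS", "VS", n_vs), ("MCS-", "MCSM", n_mcs_minus)):
        n_cmd = int(round(cmd_fraction * count))
        flags = np.zeros(count, dtype=bool)
        if n_cmd > 0:
            flags[plan_rng.choice(count, size=n_cmd, replace=False)] = True
        for k in range(count):
            specs.append((f"{prefix}{k + 1:03d}", group, bool(flags[k])))

    subject_seeds = root.spawn(len(specs))
    cohort: list[CohortSubject] = []
    for (sid, diagnosis, responder), sseq in zip(specs, subject_seeds):
        srng = np.random.default_rng(sseq)
        gose = None
        if diagnosis != "HC":
            p = favorable_p_responder if responder else favorable_p_nonresponder
            gose = _draw_gose(srng, p)
        profile = SubjectProfile(
            subject_id=sid,
            diagnosis=diagnosis,
            responder=responder,
            gose_6mo=gose,
            **profile_kwargs,
        )
        sub_seed = int(srng.integers(0, 2**63 - 1))
        rec, truth = simulate_subject(
            profile, schedule=schedule, montage=montage, seed=sub_seed, noise=noise
        )
        cohort.append(CohortSubject(profile=profile, recording=rec, truth=truth))
    return cohort
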