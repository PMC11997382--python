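"""ROI averaging, epoching, baseline correction, block averaging and the
seven-feature descriptor per chromophore per condition.

Conventions (fixed here, used by the classifier and all tests):

* Epochs span -5..40 s around each task onset; at 11 Hz that is 496 samples
  (495 intervals plus the start sample). Onsets map to samples by rounding.
* Feature windows are half-open ``[start, end)`` seconds relative to task
  onset; the rest condition's window ``[25, 40)`` is 5-20 s after the rest
  command, which starts when the 20 s task period ends.
* Moment estimators use 1/n central moments with non-excess kurtosis
  (m4/m2^2); the variance feature alone uses the conventional n-1 sample
  variance. A zero-variance window yields skewness = kurtosis = 0.
* "peak" is the window maximum for both chromophores.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import EpochingError, MissingROIError, WindowError
from .montage import ParadigmSchedule, sample_index
from .recording import HbRecording

EPOCH_PRE_S = 5.0
EPOCH_POST_S = 40.0

FEATURE_NAMES = (
    "kurtosis",
    "mean",
    "median",
    "peak",
    "peak_to_peak",
    "skewness",
    "variance",
)

TASK_WINDOW_S = (5.0, 20.0)
REST_WINDOW_S = (25.0, 40.0)

CONDITION_LABELS = {"imagery": 1, "rest": 0}


@dataclass
class ROISeries:
    roi_id: str
    chromophore: str
    values: np.ndarray
    sampling_rate_hz: float
    n_channels_averaged: int


@dataclass
class Epoch:
    roi_id: str
    chromophore: str
    values: np.ndarray  # covers [-EPOCH_PRE_S, EPOCH_POST_S]
    sampling_rate_hz: float
    baseline_corrected: bool = False

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sampling_rate_hz - EPOCH_PRE_S


@dataclass
class BlockAverageEpoch(Epoch):
    n_blocks_averaged: int = 1


@dataclass
class FeatureVector:
    subject_id: str
    roi_id: str
    condition: str  # "imagery" | "rest"
    values: dict[tuple[str, str], float]  # (chromophore, feature) -> value

    @property
    def label(self) -> int:
        return CONDITION_LABELS[self.condition]


def roi_average(
    hb: HbRecording,
    roi_map: dict[str, frozenset[int]],
    rois=None,
    on_missing: str = "skip",
) -> tuple[list[ROISeries], list[str]]:
    """Unweighted mean over each region's retained channels, per chromophore.

    Returns the series plus the list of regions skipped because no channel
    survived quality control; with ``on_missing="raise"`` a missing region is
    an error instead.
    """
    rois = list(roi_map) if rois is None else list(rois)
    retained = set(hb.channel_ids)
    out: list[ROISeries] = []
    skipped: list[str] = []
    for roi in rois:
        chans = sorted(roi_map[roi] & retained)
        if not chans:
            if on_missing == "raise":
                raise MissingROIError(f"no retained channels in {roi}")
            skipped.append(roi)
            continue
        idx = [hb.channel_index(c) for c in chans]
        mean = hb.conc_um[idx].mean(axis=0)  # (2, n_t)
        for k, chrom in enumerate(hb.chromophores):
            out.append(
                ROISeries(
                    roi_id=roi,
                    chromophore=chrom,
                    values=mean[k].copy(),
                    sampling_rate_hz=hb.sampling_rate_hz,
                    n_channels_averaged=len(chans),
                )
            )
    return out, skipped


def epoch_length(sampling_rate_hz: float) -> int:
    return sample_index(EPOCH_PRE_S + EPOCH_POST_S, sampling_rate_hz) + 1


def epoch_blocks(roi_series: ROISeries, schedule: ParadigmSchedule) -> list[Epoch]:
    """Cut one -5..40 s epoch per task event."""
    fs = roi_series.sampling_rate_hz
    n = len(roi_series.values)
    n_epoch = epoch_length(fs)
    epochs: list[Epoch] = []
    for onset in schedule.task_onsets:
        start = sample_index(onset - EPOCH_PRE_S, fs)
        stop = start + n_epoch
        if start < 0 or stop > n:
            raise EpochingError(
                f"recording ({n} samples) does not cover epoch [{start}, {stop})"
            )
        epochs.append(
            Epoch(
                roi_id=roi_series.roi_id,
                chromophore=roi_series.chromophore,
                values=roi_series.values[start:stop].copy(),
                sampling_rate_hz=fs,
            )
        )
    return epochs


def baseline_correct(epoch: Epoch) -> Epoch:
    """Subtract the mean over [-5, 0) s from the whole epoch."""
    t = epoch.times
    base = epoch.values[t < 0].mean()
    return replace(epoch, values=epoch.values - base, baseline_corrected=True)


def block_average(epochs: list[Epoch]) -> BlockAverageEpoch:
    """Pointwise mean across equal-length epochs."""
    if not epochs:
        raise EpochingError("no epochs to average")
    lengths = {len(e.values) for e in epochs}
    if len(lengths) != 1:
        raise EpochingError(f"epoch lengths differ: {sorted(lengths)}")
    stacked = np.stack([e.values for e in epochs])
    first = epochs[0]
    return BlockAverageEpoch(
        roi_id=first.roi_id,
        chromophore=first.chromophore,
        values=stacked.mean(axis=0),
        sampling_rate_hz=first.sampling_rate_hz,
        baseline_corrected=all(e.baseline_corrected for e in epochs),
        n_blocks_averaged=len(epochs),
    )


def window_features(values) -> dict[str, float]:
    """The seven descriptors of one window."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise WindowError("empty feature window")
    mean = x.mean()
    centered = x - mean
    m2 = np.mean(centered**2)
    # m2**2 can underflow to zero for near-denormal windows; treat as zero variance
    if m2 > 0 and m2**2 > 0:
        skew = float(np.mean(centered**3) / m2**1.5)
        kurt = float(np.mean(centered**4) / m2**2)
    else:
        skew = 0.0
        kurt = 0.0
    return {
        "mean": float(mean),
        "peak": float(x.max()),
        "variance": float(x.var(ddof=1)) if x.size > 1 else 0.0,
        "median": float(np.median(x)),
        "peak_to_peak": float(x.max() - x.min()),
        "skewness": skew,
        "kurtosis": kurt,
    }


def window_slice(n_samples: int, sampling_rate_hz: float,
                 window_s: tuple[float, float]) -> slice:
    """Half-open window in epoch-relative seconds -> sample slice.

    The start is rounded to a sample; the window then takes every sample
    whose time is strictly below the end.
    """
    start_s, end_s = window_s
    if end_s <= start_s:
        raise WindowError("window end must exceed start")
    start = sample_index(start_s + EPOCH_PRE_S, sampling_rate_hz)
    # largest k with k/fs - EPOCH_PRE_S < end_s
    stop = int(np.ceil((end_s + EPOCH_PRE_S) * sampling_rate_hz - 1e-9))
    if start < 0 or stop > n_samples or start >= stop:
        raise WindowError(
            f"window {window_s} s maps to samples [{start}, {stop}) outside 0..{n_samples}"
        )
    return slice(start, stop)


def extract_features(
    averages: dict[str, BlockAverageEpoch],
    subject_id: str,
    task_window_s: tuple[float, float] = TASK_WINDOW_S,
    rest_window_s: tuple[float, float] = REST_WINDOW_S,
) -> tuple[FeatureVector, FeatureVector]:
    """Per-chromophore seven-feature descriptors for the imagery and rest
    windows of one region's block-averaged epoch.

    ``averages`` maps chromophore name -> baseline-corrected block average.
    """
    rois = {e.roi_id for e in averages.values()}
    if len(rois) != 1:
        raise WindowError("all block averages must come from one region")
    roi_id = rois.pop()
    out: dict[str, dict[tuple[str, str], float]] = {"imagery": {}, "rest": {}}
    for chrom, epoch in averages.items():
        n = len(epoch.values)
        for condition, win in (("imagery", task_window_s), ("rest", rest_window_s)):
            sl = window_slice(n, epoch.sampling_rate_hz, win)
            feats = window_features(epoch.values[sl])
            for name, val in feats.items():
                out[condition][(chrom, name)] = val
    return (
        FeatureVector(subject_id, roi_id, "imagery", out["imagery"]),
        FeatureVector(subject_id, roi_id, "rest", out["rest"]),
    )


def subject_feature_vectors(
    hb: HbRecording,
    roi_map: dict[str, frozenset[int]],
    schedule: ParadigmSchedule | None = None,
    rois=None,
    per_block: bool = False,
    task_window_s: tuple[float, float] = TASK_WINDOW_S,
    rest_window_s: tuple[float, float] = REST_WINDOW_S,
) -> tuple[list[FeatureVector], list[str]]:
    """Full per-subject path: ROI average -> epochs -> baseline correction ->
    block average -> features.

    ``per_block=True`` switches to one imagery + one rest vector per block
    instead of per block-average (non-default alternative reading).
    """
    schedule = schedule if schedule is not None else hb.schedule
    if schedule is None:
        raise EpochingError("no paradigm schedule attached or supplied")
    series, skipped = roi_average(hb, roi_map, rois=rois)
    by_roi: dict[str, dict[str, ROISeries]] = {}
    for s in series:
        by_roi.setdefault(s.roi_id, {})[s.chromophore] = s
    vectors: list[FeatureVector] = []
    for roi_id, chrom_map in by_roi.items():
        corrected = {
            chrom: [baseline_correct(e) for e in epoch_blocks(s, schedule)]
            for chrom, s in chrom_map.items()
        }
        if per_block:
            n_blocks = schedule.n_blocks
            for b in range(n_blocks):
                averages = {
                    chrom: block_average([eps[b]]) for chrom, eps in corrected.items()
                }
                fv_task, fv_rest = extract_features(
                    averages, hb.subject_id, task_window_s, rest_window_s
                )
                vectors.extend([fv_task, fv_rest])
        else:
            averages = {chrom: block_average(eps) for chrom, eps in corrected.items()}
            fv_task, fv_rest = extract_features(
                averages, hb.subject_id, task_window_s, rest_window_s
            )
            vectors.extend([fv_task, fv_rest])
    return vectors, skipped


def feature_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Wide table: one row per subject x region x condition.

    Columns ``{chromophore}_{feature}`` plus subject_id, roi, condition and
    the numeric label (1 = imagery, 0 = rest).
    """
    rows = []
    for fv in vectors:
        row = {
            "subject_id": fv.subject_id,
            "roi": fv.roi_id,
            "condition": fv.condition,
            "label": fv.label,
        }
        for (chrom, name), val in fv.values.items():
            row[f"{chrom}_{name}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def tidy_feature_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Long table: subject_id, roi, condition, label, chromophore, feature, value."""
    rows = []
    for fv in vectors:
        for (chrom, name), val in fv.values.items():
            rows.append(
                {
                    "subject_id": fv.subject_id,
                    "roi": fv.roi_id,
                    "condition": fv.condition,
                    "label": fv.label,
                    "chromophore": chrom,
                    "feature_name": name,
                    "value": val,
                }
            )
    return pd.DataFrame(rows)
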