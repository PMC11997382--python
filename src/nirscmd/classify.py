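"""Per-region RBF-SVM classifiers with GA-searched hyperparameters.

Training data are healthy-control feature tables (two rows per subject: the
imagery window labelled 1 and the rest window labelled 0). Cross-validation
folds partition *subjects*, so both condition rows of a subject share a
fold, and each fold is automatically label-balanced. Feature scaling is
min-max to [0, 1], fitted inside each training partition only.

The hyperparameter search is a small real-coded genetic algorithm over
(C, gamma): tournament selection, blend crossover, Gaussian mutation
clipped to the bounds, one elite, fitness = grouped k-fold CV accuracy.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import (
    FoldError,
    InvalidParameterError,
    MissingROIError,
    PredictionError,
)
from .features import FEATURE_NAMES
from .montage import MOTOR_ROIS
from .optics import CHROMOPHORES

FeatureCombo = tuple[str, ...]


def enumerate_combos(
    n_features: int = 7,
    min_size: int = 2,
    max_size: int = 7,
    feature_names: tuple[str, ...] | None = None,
) -> list[FeatureCombo]:
    """All feature subsets of size min_size..max_size, ordered by size then
    lexicographically. With the seven canonical features and sizes 2..7 this
    yields 120 combinations."""
    names = tuple(sorted(feature_names if feature_names is not None else FEATURE_NAMES[:n_features]))
    if not 1 <= min_size <= max_size <= len(names):
        raise InvalidParameterError(
            f"need 1 <= min_size <= max_size <= {len(names)}"
        )
    combos: list[FeatureCombo] = []
    for size in range(min_size, max_size + 1):
        combos.extend(itertools.combinations(names, size))
    return combos


def combo_columns(combo: FeatureCombo) -> list[str]:
    """Feature-table columns for a combo: each feature over both chromophores."""
    return [f"{chrom}_{name}" for name in combo for chrom in CHROMOPHORES]


@dataclass(frozen=True)
class SVMParams:
    C: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise InvalidParameterError("C and gamma must be positive")


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 20
    generations: int = 50
    crossover_rate: float = 0.7
    mutation_rate: float = 0.05
    c_bounds: tuple[float, float] = (0.01, 10.0)
    gamma_bounds: tuple[float, float] = (0.01, 10.0)
    seed: int = 0
    tournament_size: int = 3
    mutation_sigma_frac: float = 0.1

    def __post_init__(self) -> None:
        for lo, hi in (self.c_bounds, self.gamma_bounds):
            if lo <= 0 or hi < lo:
                raise InvalidParameterError("search bounds must be positive and ordered")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise InvalidParameterError("rates must lie in [0, 1]")


@dataclass
class MinMaxScaler2:
    """Minimal min-max scaler kept explicit so its state serialises to JSON."""

    mins: np.ndarray
    ranges: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "MinMaxScaler2":
        mins = x.min(axis=0)
        ranges = x.max(axis=0) - mins
        ranges = np.where(ranges > 0, ranges, 1.0)
        return cls(mins=mins, ranges=ranges)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.mins) / self.ranges


def _design(frame: pd.DataFrame, combo: FeatureCombo) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cols = combo_columns(combo)
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise PredictionError(f"feature table lacks columns {missing}")
    x = frame[cols].to_numpy(dtype=float)
    y = frame["label"].to_numpy(dtype=int)
    groups = frame["subject_id"].to_numpy()
    return x, y, groups


def _subject_folds(subjects: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    uniq = np.array(sorted(set(subjects.tolist())))
    if k > len(uniq):
        raise FoldError(f"k={k} folds but only {len(uniq)} subjects")
    order = rng.permutation(len(uniq))
    folds: list[list] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(uniq[idx])
    return [np.asarray(f) for f in folds]


def cv_accuracy(
    frame: pd.DataFrame,
    combo: FeatureCombo,
    params: SVMParams,
    k: int = 20,
    seed: int | None = 0,
) -> float:
    """Grouped k-fold accuracy; scaling refit inside every training split."""
    x, y, groups = _design(frame, combo)
    if len(set(y.tolist())) < 2:
        raise InvalidParameterError("training table must contain both labels")
    rng = np.random.default_rng(seed)
    folds = _subject_folds(groups, k, rng)
    correct = 0
    for fold_subjects in folds:
        test_mask = np.isin(groups, fold_subjects)
        scaler = MinMaxScaler2.fit(x[~test_mask])
        clf = SVC(C=params.C, gamma=params.gamma, kernel="rbf")
        clf.fit(scaler.transform(x[~test_mask]), y[~test_mask])
        pred = clf.predict(scaler.transform(x[test_mask]))
        correct += int((pred == y[test_mask]).sum())
    return correct / len(y)


def _clip(v: float, bounds: tuple[float, float]) -> float:
    return float(min(max(v, bounds[0]), bounds[1]))


def ga_optimize(
    frame: pd.DataFrame,
    combo: FeatureCombo,
    ga: GAConfig = GAConfig(),
    k: int = 20,
) -> tuple[SVMParams, float]:
    """Search (C, gamma) maximising CV accuracy; deterministic given the seed."""
    if not combo:
        raise InvalidParameterError("empty feature combination")
    rng = np.random.default_rng(ga.seed)
    fold_seed = int(rng.integers(0, 2**32))
    bounds = (ga.c_bounds, ga.gamma_bounds)
    sigmas = tuple(ga.mutation_sigma_frac * (hi - lo) for lo, hi in bounds)

    cache: dict[tuple[float, float], float] = {}

    def fitness(ind: tuple[float, float]) -> float:
        key = (round(ind[0], 8), round(ind[1], 8))
        if key not in cache:
            cache[key] = cv_accuracy(frame, combo, SVMParams(*ind), k=k, seed=fold_seed)
        return cache[key]

    pop = [
        tuple(rng.uniform(lo, hi) for lo, hi in bounds)
        for _ in range(ga.population_size)
    ]
    fits = [fitness(ind) for ind in pop]

    def tournament() -> tuple[float, float]:
        idx = rng.integers(0, len(pop), size=min(ga.tournament_size, len(pop)))
        best = max(idx, key=lambda i: fits[i])
        return pop[best]

    for _ in range(ga.generations):
        elite_i = int(np.argmax(fits))
        new_pop = [pop[elite_i]]
        while len(new_pop) < ga.population_size:
            p1, p2 = tournament(), tournament()
            if rng.uniform() < ga.crossover_rate:
                alpha = rng.uniform()
                child = tuple(
                    _clip(alpha * a + (1 - alpha) * b, bounds[g])
                    for g, (a, b) in enumerate(zip(p1, p2))
                )
            else:
                child = p1
            child = tuple(
                _clip(v + rng.normal(0.0, sigmas[g]), bounds[g])
                if rng.uniform() < ga.mutation_rate
                else v
                for g, v in enumerate(child)
            )
            new_pop.append(child)
        pop = new_pop
        fits = [fitness(ind) for ind in pop]

    best_i = int(np.argmax(fits))
    best = pop[best_i]
    return SVMParams(C=best[0], gamma=best[1]), float(fits[best_i])


@dataclass
class TrainedClassifier:
    roi_id: str
    combo: FeatureCombo
    params: SVMParams
    scaler: MinMaxScaler2
    model: SVC
    cv_accuracy: float
    training_frame: pd.DataFrame = field(repr=False, default=None)


def fit_classifier(
    frame: pd.DataFrame,
    roi_id: str,
    combo: FeatureCombo,
    params: SVMParams,
    cv_acc: float = float("nan"),
) -> TrainedClassifier:
    """Refit scaler + SVM on the full training table for one region."""
    x, y, _ = _design(frame, combo)
    scaler = MinMaxScaler2.fit(x)
    model = SVC(C=params.C, gamma=params.gamma, kernel="rbf")
    model.fit(scaler.transform(x), y)
    return TrainedClassifier(
        roi_id=roi_id,
        combo=combo,
        params=params,
        scaler=scaler,
        model=model,
        cv_accuracy=cv_acc,
        training_frame=frame.reset_index(drop=True),
    )


def select_model(
    frames_by_roi: dict[str, pd.DataFrame],
    combos: list[FeatureCombo],
    rois: tuple[str, ...] = MOTOR_ROIS,
    ga: GAConfig = GAConfig(),
    k: int = 20,
    on_missing: str = "skip",
) -> dict[str, TrainedClassifier]:
    """For each region, GA-optimise every combo, keep the best (ties favour
    fewer features, then lexicographic order) and refit on the full table."""
    if not combos:
        raise InvalidParameterError("no feature combinations supplied")
    models: dict[str, TrainedClassifier] = {}
    for roi in rois:
        if roi not in frames_by_roi:
            if on_missing == "raise":
                raise MissingROIError(f"no features for {roi}")
            continue
        frame = frames_by_roi[roi]
        candidates = []
        for ci, combo in enumerate(combos):
            roi_offset = sum(ord(c) for c in roi) % 997  # stable across processes
            roi_ga = GAConfig(
                **{**ga.__dict__, "seed": ga.seed + 1000 * ci + roi_offset}
            )
            params, acc = ga_optimize(frame, combo, ga=roi_ga, k=k)
            candidates.append((acc, len(combo), combo, params))
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        acc, _, combo, params = candidates[0]
        models[roi] = fit_classifier(frame, roi, combo, params, cv_acc=acc)
    return models


def decide_response(imagery_label: int, rest_label: int, rule: str = "strict") -> bool:
    """Patient-level command-following decision from the two predicted labels.

    strict: imagery predicted 1 AND rest predicted 0.
    lenient: imagery predicted 1 (rest prediction ignored).
    """
    if imagery_label not in (0, 1) or rest_label not in (0, 1):
        raise InvalidParameterError("labels must be binary")
    if rule == "strict":
        return imagery_label == 1 and rest_label == 0
    if rule == "lenient":
        return imagery_label == 1
    raise InvalidParameterError(f"unknown decision rule {rule!r}")


@dataclass(frozen=True)
class SubjectPrediction:
    subject_id: str
    roi_id: str
    imagery_label: int
    rest_label: int
    response: bool


def predict_subject(
    model: TrainedClassifier,
    imagery_features: dict[str, float],
    rest_features: dict[str, float],
    rule: str = "strict",
    subject_id: str = "",
) -> SubjectPrediction:
    """Scale with the training-set parameters, predict both condition rows and
    apply the response rule."""
    cols = combo_columns(model.combo)
    rows = []
    for feats in (imagery_features, rest_features):
        missing = [c for c in cols if c not in feats]
        if missing:
            raise PredictionError(f"missing features {missing}")
        rows.append([float(feats[c]) for c in cols])
    x = model.scaler.transform(np.asarray(rows, float))
    labels = model.model.predict(x)
    imagery_label, rest_label = int(labels[0]), int(labels[1])
    return SubjectPrediction(
        subject_id=subject_id,
        roi_id=model.roi_id,
        imagery_label=imagery_label,
        rest_label=rest_label,
        response=decide_response(imagery_label, rest_label, rule=rule),
    )


def save_model(model: TrainedClassifier, path) -> None:
    """Serialise a trained classifier to a JSON archive.

    The archive stores the combo, parameters, scaling state and the training
    rows; loading refits the SVM deterministically from those rows, so no
    binary pickle is involved.
    """
    payload = {
        "roi_id": model.roi_id,
        "combo": list(model.combo),
        "C": model.params.C,
        "gamma": model.params.gamma,
        "cv_accuracy": model.cv_accuracy,
        "scaler_mins": model.scaler.mins.tolist(),
        "scaler_ranges": model.scaler.ranges.tolist(),
        "training_frame": model.training_frame.to_dict(orient="list"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> TrainedClassifier:
    with open(path) as fh:
        payload = json.load(fh)
    frame = pd.DataFrame(payload["training_frame"])
    model = fit_classifier(
        frame,
        payload["roi_id"],
        tuple(payload["combo"]),
        SVMParams(C=payload["C"], gamma=payload["gamma"]),
        cv_acc=payload["cv_accuracy"],
    )
    model.scaler = MinMaxScaler2(
        mins=np.asarray(payload["scaler_mins"], float),
        ranges=np.asarray(payload["scaler_ranges"], float),
    )
    return model
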