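"""Single-metric EER-threshold detection with speaker-grouped k-fold CV.

Each metric is used alone as a score.  On the training folds the detector
learns (a) the orientation — whether the pathological class scores high or
low, decided by comparing class means — and (b) the threshold minimising
|FPR - FNR| over all candidate thresholds (midpoints between adjacent sorted
unique scores, plus the two infinities); the EER is (FPR + FNR)/2 there.
Efficiency is the fraction of test items classified correctly at that
operating point.  All frames of a speaker live in the same fold, so no
speaker ever appears on both sides of a split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from modspec.exceptions import ClassError, SizeError

PATHOLOGICAL, NORMAL = "pathological", "normal"


@dataclass(frozen=True)
class FoldPlan:
    """Speaker -> fold assignment for grouped k-fold CV."""

    k: int
    speaker_to_fold: dict[str, int]
    seed: int

    def fold_of(self, speakers) -> np.ndarray:
        return np.asarray([self.speaker_to_fold[s] for s in speakers])


@dataclass(frozen=True)
class EEROperatingPoint:
    """Threshold, EER and score orientation learned on training folds."""

    threshold: float
    eer: float
    orientation: str  # pathological_high | pathological_low

    def classify(self, scores: np.ndarray) -> np.ndarray:
        """Label scores; ties at the threshold go to the pathological class."""
        scores = np.asarray(scores, dtype=np.float64)
        if self.orientation == "pathological_high":
            is_path = scores >= self.threshold
        else:
            is_path = scores <= self.threshold
        return np.where(is_path, PATHOLOGICAL, NORMAL)


@dataclass(frozen=True)
class DetectionResult:
    """Per-fold efficiencies with their mean and sample SD."""

    per_fold_efficiency: list[float]
    mean_efficiency: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        eff = np.asarray(self.per_fold_efficiency, dtype=np.float64)
        object.__setattr__(self, "mean_efficiency", float(eff.mean()))
        object.__setattr__(self, "sd", float(eff.std(ddof=1)) if len(eff) > 1 else 0.0)


def assign_speaker_folds(speakers: pd.DataFrame, k: int = 7, seed: int = 0) -> FoldPlan:
    """Stratified round-robin fold assignment of speakers.

    ``speakers`` needs columns speaker_id and label.  Speakers are shuffled
    per class by the seed and dealt round-robin so every fold sees both
    classes whenever each class has >= k speakers.
    """
    speakers = speakers.drop_duplicates("speaker_id")
    if len(speakers) < k:
        raise SizeError(f"{len(speakers)} speakers cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    mapping: dict[str, int] = {}
    position = 0  # global counter: folds fill evenly even with few speakers
    for _, group in speakers.groupby("label", sort=True):
        ids = sorted(group["speaker_id"])
        rng.shuffle(ids)
        for sid in ids:
            mapping[sid] = position % k
            position += 1
    return FoldPlan(k=k, speaker_to_fold=mapping, seed=seed)


def _error_rates(scores, labels, threshold, pathological_high):
    """(FPR, FNR) at a threshold; ties classify as pathological."""
    if pathological_high:
        pred_path = scores >= threshold
    else:
        pred_path = scores <= threshold
    is_path = labels == PATHOLOGICAL
    n_path = int(is_path.sum())
    n_norm = len(labels) - n_path
    fpr = float(np.count_nonzero(pred_path & ~is_path)) / n_norm
    fnr = float(np.count_nonzero(~pred_path & is_path)) / n_path
    return fpr, fnr


def eer_point(train: pd.DataFrame) -> EEROperatingPoint:
    """Learn the EER operating point from training scores.

    ``train`` needs columns score and label with both classes present.
    Candidate thresholds are midpoints between adjacent sorted unique scores
    plus -inf/+inf; ties in |FPR - FNR| break toward the lower threshold.
    """
    scores = train["score"].to_numpy(dtype=np.float64)
    labels = train["label"].to_numpy()
    classes = set(labels)
    if classes != {NORMAL, PATHOLOGICAL}:
        raise ClassError(f"training scores must contain both classes, got {sorted(classes)}")
    path_mean = scores[labels == PATHOLOGICAL].mean()
    norm_mean = scores[labels == NORMAL].mean()
    pathological_high = bool(path_mean >= norm_mean)
    unique = np.unique(scores)
    candidates = np.concatenate(([-np.inf], (unique[:-1] + unique[1:]) / 2.0, [np.inf]))
    best = None
    for thr in candidates:  # ascending, so first strict improvement keeps the lowest
        fpr, fnr = _error_rates(scores, labels, thr, pathological_high)
        gap = abs(fpr - fnr)
        if best is None or gap < best[0] - 1e-15:
            best = (gap, thr, (fpr + fnr) / 2.0)
    _, threshold, eer = best
    return EEROperatingPoint(
        threshold=float(threshold),
        eer=float(eer),
        orientation="pathological_high" if pathological_high else "pathological_low",
    )


def efficiency_at(test: pd.DataFrame, op: EEROperatingPoint) -> float:
    """Fraction of test rows classified correctly at the operating point."""
    if len(test) == 0:
        raise SizeError("test set is empty")
    predicted = op.classify(test["score"].to_numpy(dtype=np.float64))
    return float(np.mean(predicted == test["label"].to_numpy()))


def _to_recording_level(scores: pd.DataFrame) -> pd.DataFrame:
    return (
        scores.groupby("recording_id", sort=True)
        .agg(score=("score", "mean"), label=("label", "first"), speaker_id=("speaker_id", "first"))
        .reset_index()
    )


def cv_single_metric_efficiency(
    scores: pd.DataFrame,
    plan: FoldPlan,
    level: str = "frame",
) -> DetectionResult:
    """Speaker-grouped k-fold CV of the EER detector on one metric's scores.

    ``scores`` needs columns score, label, speaker_id, recording_id.  At
    ``level='recording'`` frame scores are first averaged per recording.
    For each fold the operating point is fitted on the other folds and
    evaluated on the held-out fold.
    """
    if level not in ("frame", "recording"):
        raise SizeError(f"level must be frame or recording, got {level!r}")
    missing = set(scores["speaker_id"]) - set(plan.speaker_to_fold)
    if missing:
        raise SizeError(f"speakers missing from the fold plan: {sorted(missing)[:5]}")
    if level == "recording":
        scores = _to_recording_level(scores)
    folds = plan.fold_of(scores["speaker_id"])
    per_fold = []
    for f in range(plan.k):
        train = scores[folds != f]
        test = scores[folds == f]
        if len(test) == 0:
            continue
        train_spk = set(train["speaker_id"])
        test_spk = set(test["speaker_id"])
        assert not (train_spk & test_spk), "speaker leakage across the fold split"
        try:
            op = eer_point(train)
        except ClassError as exc:
            raise ClassError(f"fold {f}: {exc}") from exc
        per_fold.append(efficiency_at(test, op))
    return DetectionResult(per_fold_efficiency=per_fold)
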