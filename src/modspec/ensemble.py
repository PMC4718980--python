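"""GMM ensemble over the six metrics, and feature-association matrices.

Classification fits one diagonal-covariance Gaussian mixture per class on
z-scored feature vectors (standardization learned on the training folds only)
and assigns the class with the larger log-likelihood.  Speaker-grouped CV
reports mean efficiency per mixture size together with a 95%
normal-approximation binomial half-width on the pooled decisions.

Association between metrics is summarised two ways: the Pearson correlation
matrix (with p-values) and the relative mutual information matrix — the
plug-in histogram MI of each pair, equal-width bins over the observed range,
divided by log2(n_bins).  The diagonal is then the normalized marginal
entropy, below 1 for peaked distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from modspec.detector import NORMAL, PATHOLOGICAL, DetectionResult, FoldPlan
from modspec.exceptions import ClassError, DegenerateFeatureError, SizeError
from modspec.metrics import METRIC_NAMES


@dataclass(frozen=True)
class GMMDetectorSpec:
    """Mixture size, covariance family, seed and variance floor."""

    n_components: int = 8
    covariance: str = "diagonal"
    seed: int = 0
    regularization: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise SizeError("n_components must be >= 1")
        if self.covariance != "diagonal":
            raise SizeError(f"only diagonal covariance is supported, got {self.covariance!r}")


@dataclass
class GMMDetector:
    """Per-class GMMs plus the training standardization."""

    spec: GMMDetectorSpec
    feature_names: tuple
    mean_: np.ndarray
    scale_: np.ndarray
    gmm_normal: GaussianMixture
    gmm_pathological: GaussianMixture

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_

    def log_likelihood_ratio(self, features: pd.DataFrame) -> np.ndarray:
        """Per-row log p(x | pathological) - log p(x | normal)."""
        X = self._standardize(features[list(self.feature_names)].to_numpy(dtype=np.float64))
        return self.gmm_pathological.score_samples(X) - self.gmm_normal.score_samples(X)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        llr = self.log_likelihood_ratio(features)
        return np.where(llr >= 0, PATHOLOGICAL, NORMAL)


def _feature_matrix(features: pd.DataFrame, names) -> np.ndarray:
    X = features[list(names)].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise DegenerateFeatureError("feature table contains non-finite values")
    return X


def fit_gmm_detector(
    train: pd.DataFrame,
    spec: GMMDetectorSpec,
    feature_names=METRIC_NAMES,
) -> GMMDetector:
    """Fit the per-class mixtures; both classes need >= n_components rows."""
    labels = train["label"].to_numpy()
    if set(labels) != {NORMAL, PATHOLOGICAL}:
        raise ClassError(f"training data must contain both classes, got {sorted(set(labels))}")
    X = _feature_matrix(train, feature_names)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xz = (X - mean) / scale
    models = {}
    for cls in (NORMAL, PATHOLOGICAL):
        Xc = Xz[labels == cls]
        if len(Xc) < spec.n_components:
            raise SizeError(
                f"class {cls} has {len(Xc)} rows < {spec.n_components} mixture components"
            )
        models[cls] = GaussianMixture(
            n_components=spec.n_components,
            covariance_type="diag",
            reg_covar=spec.regularization,
            random_state=spec.seed,
            init_params="kmeans",
            max_iter=200,
        ).fit(Xc)
    return GMMDetector(
        spec=spec,
        feature_names=tuple(feature_names),
        mean_=mean,
        scale_=scale,
        gmm_normal=models[NORMAL],
        gmm_pathological=models[PATHOLOGICAL],
    )


def cv_gmm_efficiency(
    features: pd.DataFrame,
    plan: FoldPlan,
    component_grid=(4, 8, 16, 32, 64),
    seed: int = 0,
    feature_names=METRIC_NAMES,
) -> dict[int, dict]:
    """Speaker-grouped CV of the GMM ensemble per mixture size.

    Returns {n_components: {"result": DetectionResult,
    "ci_halfwidth": float, "pooled_efficiency": float}} where the half-width
    is 1.96 * sqrt(p*(1-p)/n) on the pooled decision count.
    """
    folds = plan.fold_of(features["speaker_id"])
    out: dict[int, dict] = {}
    for n_comp in component_grid:
        spec = GMMDetectorSpec(n_components=int(n_comp), seed=seed)
        per_fold = []
        n_correct = 0
        n_total = 0
        for f in range(plan.k):
            train = features[folds != f]
            test = features[folds == f]
            if len(test) == 0:
                continue
            assert not (set(train["speaker_id"]) & set(test["speaker_id"])), (
                "speaker leakage across the fold split"
            )
            det = fit_gmm_detector(train, spec, feature_names)
            correct = det.predict(test) == test["label"].to_numpy()
            per_fold.append(float(np.mean(correct)))
            n_correct += int(correct.sum())
            n_total += len(correct)
        pooled = n_correct / n_total
        out[int(n_comp)] = {
            "result": DetectionResult(per_fold_efficiency=per_fold),
            "pooled_efficiency": pooled,
            "ci_halfwidth": binomial_halfwidth(pooled, n_total),
        }
    return out


def binomial_halfwidth(p: float, n: int, z: float = 1.96) -> float:
    """Normal-approximation 95% half-width of a proportion."""
    return float(z * np.sqrt(p * (1.0 - p) / n))


def correlation_matrix(features: pd.DataFrame, feature_names=METRIC_NAMES):
    """Pairwise Pearson correlations and two-sided p-values (6x6 DataFrames)."""
    X = _feature_matrix(features, feature_names)
    if X.shape[0] < 3:
        raise SizeError("need at least 3 rows for correlation")
    if np.any(X.std(axis=0) == 0):
        bad = [n for n, s in zip(feature_names, X.std(axis=0)) if s == 0]
        raise DegenerateFeatureError(f"zero-variance features: {bad}")
    k = len(feature_names)
    corr = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r, p = stats.pearsonr(X[:, i], X[:, j])
            corr[i, j] = corr[j, i] = r
            pval[i, j] = pval[j, i] = p
    names = list(feature_names)
    return (
        pd.DataFrame(corr, index=names, columns=names),
        pd.DataFrame(pval, index=names, columns=names),
    )


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width binning over the observed range; constant input is an error."""
    lo, hi = x.min(), x.max()
    if lo == hi:
        raise DegenerateFeatureError("constant feature cannot be discretized")
    idx = np.floor((x - lo) / (hi - lo) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def _plugin_mi(xi: np.ndarray, yi: np.ndarray, n_bins: int) -> float:
    """Plug-in MI (bits) of two discretized columns."""
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log2(joint[mask] / (px @ py)[mask])))


def relative_mi_matrix(
    features: pd.DataFrame,
    n_bins: int = 32,
    feature_names=METRIC_NAMES,
) -> pd.DataFrame:
    """Pairwise plug-in mutual information normalized by log2(n_bins).

    The diagonal equals the normalized marginal entropy H(X)/log2(n_bins),
    strictly below 1 whenever the histogram is not uniform.
    """
    if n_bins < 2:
        raise SizeError("n_bins must be >= 2")
    X = _feature_matrix(features, feature_names)
    if X.shape[0] < n_bins:
        raise SizeError(f"need at least n_bins={n_bins} rows, got {X.shape[0]}")
    disc = np.column_stack([_discretize(X[:, j], n_bins) for j in range(X.shape[1])])
    k = len(feature_names)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            out[i, j] = out[j, i] = _plugin_mi(disc[:, i], disc[:, j], n_bins) / np.log2(n_bins)
    names = list(feature_names)
    return pd.DataFrame(out, index=names, columns=names)
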