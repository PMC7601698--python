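"""Generated-image quality metric: feature cascade -> calibrated SVM ->
binned probability histograms -> KL divergence.

The idea: train a two-class SVM on handcrafted features (HOG for local
shape/appearance, LBP for gray-level-invariant texture) of *real* images.
Push equal-sized sets of real and generated images through the classifier,
histogram the predicted positive-class probabilities of each set on [0, 1],
and report KL(real ‖ generated).  A generator whose samples induce the
same classifier-response distribution as real images scores near zero.

Unlike Inception-based scores, nothing here depends on a natural-image
pretrained network, which makes the metric usable for medical images.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from skimage.feature import hog, local_binary_pattern
from sklearn.calibration import CalibratedClassifierCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FeatureParams", "BinnedDistribution",
    "hog_features", "lbp_features", "cascade", "extract_features",
    "train_eval_classifier", "probability_distribution",
    "kl_divergence", "evaluate_generated",
    "save_classifier", "load_classifier",
]


@dataclass
class FeatureParams:
    """HOG + LBP extraction parameters (the standard defaults of each
    descriptor)."""

    hog_orientations: int = 9
    hog_cell: int = 8              # pixels per cell (square)
    hog_block: int = 2             # cells per block (square), L2 block norm
    lbp_points: int = 8
    lbp_radius: float = 1.0


@dataclass
class BinnedDistribution:
    """Normalized histogram of classifier probabilities on [0, 1]."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.probabilities = np.asarray(self.probabilities, float)
        if len(self.probabilities) != len(self.bin_edges) - 1:
            raise ValueError("need one probability per bin")
        if np.any(self.probabilities < 0):
            raise ValueError("bin probabilities must be nonnegative")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("bin probabilities must sum to 1")

    @property
    def n_bins(self) -> int:
        return len(self.probabilities)


def _as_gray2d(img) -> np.ndarray:
    a = np.asarray(img, dtype=float)
    if a.ndim == 3 and a.shape[-1] == 1:
        a = a[..., 0]
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {a.shape}")
    return a


def hog_features(img, params: FeatureParams | None = None) -> np.ndarray:
    """Histogram-of-oriented-gradients descriptor (block-normalized, fixed
    length for fixed geometry)."""
    params = params or FeatureParams()
    a = _as_gray2d(img)
    if min(a.shape) < params.hog_cell:
        raise ValueError(
            f"image {a.shape} smaller than one {params.hog_cell}x{params.hog_cell} HOG cell"
        )
    return hog(
        a,
        orientations=params.hog_orientations,
        pixels_per_cell=(params.hog_cell, params.hog_cell),
        cells_per_block=(params.hog_block, params.hog_block),
        block_norm="L2",
        feature_vector=True,
    )


def lbp_features(img, params: FeatureParams | None = None) -> np.ndarray:
    """Normalized histogram of uniform rotation-invariant local binary
    patterns (invariant to monotone gray-level changes)."""
    params = params or FeatureParams()
    a = _as_gray2d(img)
    # LBP thresholds neighbour vs centre: integer input avoids float-tie noise
    if np.allclose(a, np.rint(a)):
        a = np.rint(a).astype(np.int64)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", UserWarning)
        codes = local_binary_pattern(a, P=params.lbp_points, R=params.lbp_radius,
                                     method="uniform")
    n_bins = params.lbp_points + 2
    hist, _ = np.histogram(codes, bins=np.arange(n_bins + 1) - 0.5)
    return hist / hist.sum()


def cascade(hog_vec: np.ndarray, lbp_vec: np.ndarray) -> np.ndarray:
    """Concatenate the two descriptor segments, HOG first then LBP."""
    return np.concatenate([np.asarray(hog_vec, float), np.asarray(lbp_vec, float)])


def extract_features(images, params: FeatureParams | None = None) -> np.ndarray:
    """Cascaded HOG+LBP features for a stack of images, one row per image."""
    params = params or FeatureParams()
    return np.stack([cascade(hog_features(i, params), lbp_features(i, params)) for i in images])


def train_eval_classifier(features: np.ndarray, labels, seed: int = 0, C: float = 1.0):
    """RBF-kernel SVM with calibrated probability outputs on standardized
    features.  Both classes must be present."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    svm = SVC(kernel="rbf", C=C, random_state=seed)
    model = Pipeline([
        ("scale", StandardScaler()),
        ("svm", CalibratedClassifierCV(svm, ensemble=False)),
    ])
    model.fit(np.asarray(features, float), labels)
    return model


def probability_distribution(model, images, n_bins: int = 10,
                             params: FeatureParams | None = None,
                             smoothing: float | None = None) -> BinnedDistribution:
    """Histogram of predicted positive-class probabilities.

    Equal-width bins on [0, 1]; additive smoothing (default 1/(10·n_bins)
    per bin) keeps every bin strictly positive before normalization so the
    histogram can safely sit in the denominator of a KL divergence.
    """
    images = np.asarray(images)
    if images.shape[0] == 0:
        raise ValueError("empty image set")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    feats = extract_features(images, params)
    probs = model.predict_proba(feats)[:, 1]
    return _binned(probs, n_bins, smoothing)


def _binned(probs: np.ndarray, n_bins: int, smoothing: float | None) -> BinnedDistribution:
    eps = (1.0 / (10.0 * n_bins)) if smoothing is None else smoothing
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(np.clip(probs, 0.0, 1.0), bins=edges)
    weights = counts / counts.sum() + eps
    return BinnedDistribution(edges, weights / weights.sum())


def kl_divergence(P: BinnedDistribution, Q: BinnedDistribution) -> float:
    """KL(P ‖ Q) = Σ_i P_i ln(P_i / Q_i) in nats; zero-probability P bins
    contribute nothing.  P and Q must share their binning."""
    if P.n_bins != Q.n_bins or not np.allclose(P.bin_edges, Q.bin_edges):
        raise ValueError("distributions must share identical binning")
    p, q = P.probabilities, Q.probabilities
    if np.any((p > 0) & (q == 0)):
        raise ValueError("Q must be positive wherever P is (use smoothing)")
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def evaluate_generated(real_images, fake_images, model, n_bins: int = 10,
                       params: FeatureParams | None = None) -> float:
    """KL(real ‖ generated) of classifier-probability histograms.

    The two sets must be the same size so the histograms are comparable.
    """
    real_images = np.asarray(real_images)
    fake_images = np.asarray(fake_images)
    if real_images.shape[0] != fake_images.shape[0]:
        raise ValueError(
            f"real and generated counts differ: {real_images.shape[0]} vs {fake_images.shape[0]}"
        )
    P = probability_distribution(model, real_images, n_bins, params)
    Q = probability_distribution(model, fake_images, n_bins, params)
    return kl_divergence(P, Q)


# ---------------------------------------------------------------------------
# persistence (model + feature-parameter sidecar, self-describing)
# ---------------------------------------------------------------------------

def save_classifier(model, path: str | Path, params: FeatureParams | None = None) -> None:
    import json
    import joblib
    path = Path(path)
    joblib.dump(model, path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"feature_params": asdict(params or FeatureParams())}, indent=2))


def load_classifier(path: str | Path):
    import json
    import joblib
    path = Path(path)
    model = joblib.load(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    params = FeatureParams()
    if sidecar.exists():
        params = FeatureParams(**json.loads(sidecar.read_text())["feature_params"])
    return model, params
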