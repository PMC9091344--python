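"""Seven-class shape classification of cell crops.

Two interchangeable backends share one preprocessing contract:

``moments``
    Morphometric features of the segmented silhouette — area fraction,
    circularity, eccentricity, solidity, extent, a mirror-symmetry score
    about the flow axis, and the seven log-scaled Hu moments — fed to a
    linear discriminant.  Fast, fully deterministic, interpretable.

``mlp``
    A small dense neural network (one hidden layer) on the normalized,
    downsampled pixel crop.  Higher capacity; deterministic given the seed.

Preprocessing (documented so any backend can reuse it): estimate the crop's
background level from its border pixels, convert to a positive cell signal
(works for raw bright-field crops, dark cell on light background, and for
background-subtracted crops, bright cell on zero background), normalize to
peak 1, and resize to ``input_side`` pixels.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import joblib
import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, moments_hu, regionprops
from skimage.transform import resize
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import FormatError, RejectedInputError
from .shapes import CLASS_ORDER, HEALTHY_CLASSES, ShapeClass

MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ClassifierConfig:
    """Backend choice and training hyperparameters."""

    backend: str = "moments"  # "moments" or "mlp"
    input_side: int = 48  # preprocessing resize for feature extraction
    pixel_side: int = 28  # mlp pixel-input resolution
    hidden_units: int = 96
    learning_rate: float = 1e-3
    epochs: int = 400
    batch_size: int = 64
    holdout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("moments", "mlp"):
            raise RejectedInputError(f"unknown classifier backend {self.backend!r}")


@dataclass
class ClassifiedCell:
    """One track's predicted shape class and its 7-class probability vector."""

    track_id: int
    predicted: ShapeClass
    probabilities: np.ndarray  # aligned with shapes.CLASS_ORDER


def preprocess_crop(crop: np.ndarray, input_side: int = 48) -> np.ndarray:
    """Canonical positive-signal crop, peak-normalized, resized to a square."""
    crop = np.asarray(crop, dtype=np.float64)
    if crop.size == 0:
        raise RejectedInputError("empty crop")
    if np.isnan(crop).any():
        raise RejectedInputError("crop contains NaN")
    border = np.concatenate([crop[0], crop[-1], crop[:, 0], crop[:, -1]])
    sig = crop - np.median(border)
    if -sig.min() > sig.max():
        sig = -sig  # cell darker than background: flip polarity
    peak = sig.max()
    if peak > 0:
        sig = sig / peak
    return resize(sig, (input_side, input_side), anti_aliasing=True)


def _flip_symmetry(mask: np.ndarray) -> float:
    """IoU of the silhouette with its mirror about the flow (horizontal) axis."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sub = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    flipped = sub[::-1]
    inter = np.logical_and(sub, flipped).sum()
    union = np.logical_or(sub, flipped).sum()
    return float(inter / union) if union else 0.0


N_FEATURES = 13


def features_from_crop(processed: np.ndarray) -> np.ndarray:
    """Morphometric feature vector of a preprocessed crop (length 13)."""
    try:
        thr = threshold_otsu(processed)
    except ValueError:  # constant image
        return np.zeros(N_FEATURES)
    mask = processed > max(thr, 0.2)
    if mask.sum() < 8:
        return np.zeros(N_FEATURES)
    lab = label(mask)
    regions = regionprops(lab)
    region = max(regions, key=lambda r: r.area)
    mask = lab == region.label
    area_frac = region.area / mask.size
    perim = max(region.perimeter, 1.0)
    circularity = 4.0 * np.pi * region.area / perim**2
    hu = moments_hu(mask.astype(float))
    log_hu = -np.sign(hu) * np.log10(np.abs(hu) + 1e-30)
    return np.concatenate(
        [
            [
                area_frac,
                circularity,
                region.eccentricity,
                region.solidity,
                region.extent,
                _flip_symmetry(mask),
            ],
            log_hu,
        ]
    )


class ShapeClassifier:
    """Trained shape classifier; use :func:`train_classifier` to build one."""

    def __init__(self, config: ClassifierConfig, estimator, training_hash: str):
        self.config = config
        self.estimator = estimator
        self.training_hash = training_hash
        self.holdout_accuracy_: float | None = None
        self.holdout_confusion_: np.ndarray | None = None

    # -- internal -----------------------------------------------------------
    def _design_matrix(self, crops) -> np.ndarray:
        rows = []
        for crop in crops:
            proc = preprocess_crop(crop, self.config.input_side)
            if self.config.backend == "moments":
                rows.append(features_from_crop(proc))
            else:
                side = self.config.pixel_side
                rows.append(resize(proc, (side, side), anti_aliasing=True).ravel())
        return np.asarray(rows)

    def _proba(self, X: np.ndarray) -> np.ndarray:
        """Probabilities expanded to the full fixed 7-class order."""
        raw = self.estimator.predict_proba(X)
        present = list(self.estimator.classes_)
        out = np.zeros((X.shape[0], len(CLASS_ORDER)))
        for j, cls in enumerate(CLASS_ORDER):
            if cls.value in present:
                out[:, j] = raw[:, present.index(cls.value)]
        return out

    # -- public -------------------------------------------------------------
    def predict_proba(self, crops) -> np.ndarray:
        return self._proba(self._design_matrix(crops))


def _make_estimator(config: ClassifierConfig):
    if config.backend == "moments":
        return make_pipeline(StandardScaler(), LinearDiscriminantAnalysis())
    return make_pipeline(
        StandardScaler(),
        MLPClassifier(
            hidden_layer_sizes=(config.hidden_units,),
            learning_rate_init=config.learning_rate,
            max_iter=config.epochs,
            batch_size=config.batch_size,
            random_state=config.seed,
        ),
    )


def train_classifier(
    crops, labels, config: ClassifierConfig = ClassifierConfig()
) -> ShapeClassifier:
    """Train a classifier and report held-out accuracy on a stratified split.

    Reproducible given ``config.seed``; rejects labels outside the seven-class
    set and degenerate single-class training sets.
    """
    labels = [ShapeClass(l) for l in labels]
    if len(set(labels)) < 2:
        raise RejectedInputError("training needs at least 2 classes")
    if len(labels) != len(crops):
        raise RejectedInputError("crops and labels length mismatch")

    crops_arr = np.asarray(crops, dtype=np.float32)
    digest = hashlib.sha256(crops_arr.tobytes()).hexdigest()[:16]
    model = ShapeClassifier(config, _make_estimator(config), digest)

    X = model._design_matrix(crops_arr)
    y = np.array([l.value for l in labels])
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y,
        test_size=config.holdout_fraction,
        stratify=y,
        random_state=config.seed,
    )
    model.estimator.fit(X_tr, y_tr)
    y_hat = model.estimator.predict(X_te)
    model.holdout_accuracy_ = float(accuracy_score(y_te, y_hat))
    model.holdout_confusion_ = confusion_matrix(
        y_te, y_hat, labels=[c.value for c in CLASS_ORDER]
    )
    return model


def classify(model: ShapeClassifier, crop: np.ndarray) -> tuple[ShapeClass, np.ndarray]:
    """Label one crop; returns (class, 7-probability vector in fixed order)."""
    probs = model.predict_proba([crop])[0]
    return CLASS_ORDER[int(np.argmax(probs))], probs


def classify_batch(
    model: ShapeClassifier, crops
) -> tuple[list[ShapeClass], np.ndarray]:
    """Label many crops preserving order."""
    probs = model.predict_proba(crops)
    labels = [CLASS_ORDER[i] for i in np.argmax(probs, axis=1)]
    return labels, probs


def classify_tracks(
    model: ShapeClassifier, track_crops: dict[int, list[np.ndarray]]
) -> list[ClassifiedCell]:
    """One label per track: majority vote over its per-frame crops.

    Ties are broken by the larger mean probability of the tied classes.
    """
    out: list[ClassifiedCell] = []
    for track_id, crops in track_crops.items():
        if len(crops) == 0:
            raise RejectedInputError(f"track {track_id} has no crops")
        labels, probs = classify_batch(model, crops)
        counts = np.zeros(len(CLASS_ORDER))
        for l in labels:
            counts[CLASS_ORDER.index(l)] += 1
        mean_probs = probs.mean(axis=0)
        best = np.flatnonzero(counts == counts.max())
        winner = best[int(np.argmax(mean_probs[best]))]
        out.append(
            ClassifiedCell(
                track_id=track_id,
                predicted=CLASS_ORDER[winner],
                probabilities=mean_probs,
            )
        )
    return out


def healthy_pathological(label: ShapeClass) -> str:
    """Binarize a class label into the fixed healthy/pathological partition."""
    return "healthy" if label in HEALTHY_CLASSES else "pathological"


# -- serialization -----------------------------------------------------------


def save_model(model: ShapeClassifier, path) -> None:
    """Serialize to a single file plus a JSON sidecar (config, classes, hash)."""
    path = Path(path)
    joblib.dump(model.estimator, path)
    sidecar = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "config": asdict(model.config),
        "class_order": [c.value for c in CLASS_ORDER],
        "training_hash": model.training_hash,
        "holdout_accuracy": model.holdout_accuracy_,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )


def load_model(path) -> ShapeClassifier:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"model sidecar {sidecar_path} missing")
    sidecar = json.loads(sidecar_path.read_text())
    if sidecar.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise FormatError(
            f"model schema version {sidecar.get('schema_version')} unsupported"
        )
    if sidecar["class_order"] != [c.value for c in CLASS_ORDER]:
        raise FormatError("model class order does not match this package version")
    model = ShapeClassifier(
        ClassifierConfig(**sidecar["config"]),
        joblib.load(path),
        sidecar["training_hash"],
    )
    model.holdout_accuracy_ = sidecar.get("holdout_accuracy")
    return model
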