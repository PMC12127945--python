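"""Stage 4: frontal-vs-lateral projection classification and header checks.

The classifier is a regularized logistic regression over engineered image
features (downsampled intensities, mirror-symmetry score, profile
moments). The model handle is an interface: any object exposing
``predict_score(image) -> P(frontal)`` can stand behind
:func:`predict_projection`, so a convolutional backend can be swapped in.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import joblib
import numpy as np
from skimage.transform import resize
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .records import ACTION_FLAG, ACTION_PASS, QCResult

MODEL_FORMAT_VERSION = 1
FRONTAL, LATERAL = "frontal", "lateral"
_DOWNSAMPLE = 32

# Editable token tables for Series Description parsing. Lateral tokens take
# precedence when both appear ("PA AND LATERAL" names a lateral acquisition
# in a combined study description more often than not, and mislabeling a
# lateral as frontal is the costlier error).
FRONTAL_TOKENS = ("PA", "AP", "FRONTAL")
LATERAL_TOKENS = ("LAT", "LATERAL", "LL", "RL")


@dataclass(frozen=True)
class ProjectionCall:
    label: str
    score: float  # probability of frontal
    threshold_used: float

    def __post_init__(self) -> None:
        if (self.label == FRONTAL) != (self.score >= self.threshold_used):
            raise ValueError("label inconsistent with score/threshold")


@dataclass(frozen=True)
class HeaderProjection:
    declared: str  # frontal | lateral | absent
    matched_token: Optional[str] = None

    def __post_init__(self) -> None:
        if self.declared == "absent" and self.matched_token is not None:
            raise ValueError("absent declaration cannot carry a token")


def extract_projection_features(image: np.ndarray) -> np.ndarray:
    """Fixed-length feature vector: 32x32 intensities, a vertical-mirror
    symmetry score, and row/column profile moments. Length is independent
    of input resolution."""
    image = np.asarray(image, dtype=np.float64)
    small = resize(image, (_DOWNSAMPLE, _DOWNSAMPLE), anti_aliasing=True,
                   mode="reflect")
    sym = 1.0 - float(np.mean(np.abs(small - small[:, ::-1])))
    feats = [small.ravel(), np.array([sym])]
    for profile in (small.mean(axis=1), small.mean(axis=0)):
        idx = np.arange(profile.size)
        total = profile.sum()
        com = float((idx * profile).sum() / total) / profile.size if total > 0 else 0.5
        q = profile.size // 4
        feats.append(np.array([profile.mean(), profile.std(), com,
                               float(profile[-q:].mean() - profile[:q].mean())]))
    return np.concatenate(feats)


FEATURE_LENGTH = _DOWNSAMPLE * _DOWNSAMPLE + 1 + 8


@dataclass
class ProjectionModel:
    """Versioned handle around the fitted classifier."""

    estimator: Pipeline
    feature_hash: str
    version: int = MODEL_FORMAT_VERSION

    def predict_score(self, image: np.ndarray) -> float:
        x = extract_projection_features(image)
        if x.size != FEATURE_LENGTH:
            raise ValueError("feature-length mismatch with trained model")
        idx = list(self.estimator.classes_).index(FRONTAL)
        return float(self.estimator.predict_proba(x[None, :])[0, idx])

    def save(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        joblib.dump({"version": self.version, "feature_hash": self.feature_hash,
                     "estimator": self.estimator}, path)
        return path

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ProjectionModel":
        d = joblib.load(path)
        model = cls(estimator=d["estimator"], feature_hash=d["feature_hash"],
                    version=d["version"])
        if model.feature_hash != _feature_spec_hash():
            raise ValueError("model was trained with an incompatible feature spec")
        return model


def _feature_spec_hash() -> str:
    sig = f"v{MODEL_FORMAT_VERSION}:downsample={_DOWNSAMPLE}:len={FEATURE_LENGTH}"
    return hashlib.sha256(sig.encode()).hexdigest()[:16]


def train_projection_model(images: Sequence[np.ndarray], labels: Sequence[str],
                           seed: int = 0, C: float = 1.0) -> ProjectionModel:
    """Fit the frontal/lateral classifier. Deterministic given ``seed``.

    Requires at least 50 labeled images with both classes present.
    """
    labels = list(labels)
    if len(images) != len(labels):
        raise ValueError("images and labels must have equal length")
    if len(labels) < 50:
        raise ValueError(f"need at least 50 training images, got {len(labels)}")
    classes = set(labels)
    if classes != {FRONTAL, LATERAL}:
        raise ValueError(f"both classes must be present, got {sorted(classes)}")
    X = np.stack([extract_projection_features(im) for im in images])
    # center only: the features share the [0, 1] intensity scale, and
    # per-feature variance scaling would blow up low-variance regions
    # (e.g. flat corners) into huge z-scores on out-of-distribution inputs
    est = Pipeline([
        ("scale", StandardScaler(with_std=False)),
        ("clf", LogisticRegression(C=C, max_iter=2000, random_state=seed)),
    ])
    est.fit(X, np.array(labels))
    return ProjectionModel(estimator=est, feature_hash=_feature_spec_hash())


def predict_projection(model: ProjectionModel, image: np.ndarray,
                       threshold: float = 0.5) -> ProjectionCall:
    score = model.predict_score(image)
    label = FRONTAL if score >= threshold else LATERAL
    return ProjectionCall(label=label, score=score, threshold_used=threshold)


_TOKEN_SPLIT = re.compile(r"[^A-Z0-9]+")


def parse_series_description(text: Optional[str]) -> HeaderProjection:
    """Case-insensitive token match of a Series Description string.

    Lateral tokens take precedence over frontal tokens when both occur.
    """
    if text is None or not str(text).strip():
        return HeaderProjection(declared="absent")
    tokens = [t for t in _TOKEN_SPLIT.split(str(text).upper()) if t]
    for token in tokens:
        if token in LATERAL_TOKENS:
            return HeaderProjection(declared=LATERAL, matched_token=token)
    for token in tokens:
        if token in FRONTAL_TOKENS:
            return HeaderProjection(declared=FRONTAL, matched_token=token)
    return HeaderProjection(declared="absent")


def consistency_check(declared: HeaderProjection,
                      predicted: ProjectionCall) -> QCResult:
    """Flag images whose header projection disagrees with the image-based
    call; an absent declaration passes."""
    evidence = {"declared": declared.declared, "predicted": predicted.label,
                "score": round(predicted.score, 6)}
    if declared.declared in ("absent", predicted.label):
        return QCResult(stage="projection_consistency", action=ACTION_PASS,
                        reasons=[], evidence=evidence)
    return QCResult(stage="projection_consistency", action=ACTION_FLAG,
                    reasons=["metadata_mismatch"], evidence=evidence)


def header_token_stats(descriptions: Sequence[Optional[str]]) -> Tuple[float, int]:
    """Fraction of Series Descriptions containing any projection token, and
    the count that did."""
    if not descriptions:
        return 0.0, 0
    n_with = sum(parse_series_description(d).declared != "absent"
                 for d in descriptions)
    return n_with / len(descriptions), n_with
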