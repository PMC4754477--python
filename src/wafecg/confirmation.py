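"""Confirmation-function classification of ECG feature vectors.

A rhythm class is represented by an *arrhythmia model*: the element-wise
average of feature vectors from (typically fifteen) training segments of
that class. A tested vector Y is compared against a hypothesized model x
(the target class, CHF) and a background model b (an opposing rhythm:
NSR, AF or PEB) by three independent confirmation functions:

* PRDS — percentage root-mean-square difference score,
  ``100 * ||Y - m|| / ||Y||``; confirms when PRDS against the hypothesized
  model is strictly smaller than against the background (ratio < 1).
* LDSR — log of the ratio of squared distances to the two models,
  ``log(||Y - x||^2 / ||Y - b||^2)``; confirms when <= 0.
* CCR — ratio of Pearson correlations, ``CC(Y,x) / CC(Y,b)``; confirms
  when strictly > 1.

The final decision is the conjunction: the segment is accepted as the
hypothesized class only if all three functions confirm. Boundary ties
(PRDS ratio = 1, CCR = 1) do not confirm; LDSR = 0 does.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .exceptions import IncompatibleFeaturesError, UndefinedScoreError
from .features import FeatureVector, WaveletConfig

__all__ = [
    "ArrhythmiaModel",
    "ConfirmationResult",
    "build_model",
    "prds",
    "ldsr",
    "ccr",
    "confirm",
    "save_model",
    "load_model",
]

_EPS = 1e-12


@dataclass
class ArrhythmiaModel:
    """Class-average feature vector serving as hypothesized or background model."""

    mean_vector: np.ndarray
    class_label: str
    n_training: int
    config: WaveletConfig
    extractor: str = "WAFE"

    def __post_init__(self) -> None:
        self.mean_vector = np.asarray(self.mean_vector, dtype=np.float64)
        if self.n_training < 1:
            raise IncompatibleFeaturesError("a model needs at least one training vector")


@dataclass
class ConfirmationResult:
    """Scores, per-function verdicts and the combined decision for one segment."""

    prds_x: float
    prds_b: float
    prds_ratio: float
    ldsr: float
    cc_x: float
    cc_b: float
    ccr: float
    confirm_prds: bool
    confirm_ldsr: bool
    confirm_ccr: bool
    confirmed: bool
    score: float  # continuous decision score (-LDSR); higher = more like x

    def as_dict(self) -> dict:
        return asdict(self)


def build_model(vectors: list[FeatureVector], class_label: str) -> ArrhythmiaModel:
    """Average feature vectors of one class into an arrhythmia model."""
    if not vectors:
        raise IncompatibleFeaturesError("cannot build a model from zero vectors")
    extractor = vectors[0].extractor
    length = len(vectors[0].values)
    config = vectors[0].config
    for fv in vectors[1:]:
        if fv.extractor != extractor:
            raise IncompatibleFeaturesError(
                f"mixed extractors: {extractor!r} vs {fv.extractor!r}"
            )
        if len(fv.values) != length:
            raise IncompatibleFeaturesError(
                f"mixed vector lengths: {length} vs {len(fv.values)}"
            )
        if fv.config != config:
            raise IncompatibleFeaturesError("mixed wavelet configs in training vectors")
    mean = np.mean([fv.values for fv in vectors], axis=0)
    return ArrhythmiaModel(mean, class_label, len(vectors), config, extractor)


def _values(v: FeatureVector | ArrhythmiaModel | np.ndarray) -> np.ndarray:
    if isinstance(v, FeatureVector):
        return v.values
    if isinstance(v, ArrhythmiaModel):
        return v.mean_vector
    return np.asarray(v, dtype=np.float64)


def prds(y, m) -> float:
    """Percentage RMS difference between a tested vector and a model.

    ``100 * sqrt(sum((y - m)^2) / sum(y^2))``; 0 iff y == m elementwise.
    """
    yv, mv = _values(y), _values(m)
    if yv.shape != mv.shape:
        raise IncompatibleFeaturesError(f"shape mismatch {yv.shape} vs {mv.shape}")
    denom = float(np.sum(yv**2))
    if denom == 0:
        raise UndefinedScoreError("PRDS is undefined for a zero tested vector")
    return 100.0 * math.sqrt(float(np.sum((yv - mv) ** 2)) / denom)


def ldsr(y, mx, mb) -> float:
    """Log ratio of squared distances to the hypothesized vs background model.

    ``log([sum((y-x)^2) + eps] / [sum((y-b)^2) + eps])`` with eps = 1e-12
    guarding log(0); natural log (only the sign is thresholded). Negative
    values mean y lies closer to the hypothesized model. Computed as a
    difference of logs so swapping the models negates the value exactly.
    """
    yv = _values(y)
    dx = float(np.sum((yv - _values(mx)) ** 2))
    db = float(np.sum((yv - _values(mb)) ** 2))
    if dx < _EPS and db < _EPS:
        raise UndefinedScoreError("LDSR is undefined: y equals both models")
    return math.log(dx + _EPS) - math.log(db + _EPS)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    na = math.sqrt(float(np.sum(ac**2)))
    nb = math.sqrt(float(np.sum(bc**2)))
    if na == 0 or nb == 0:
        raise UndefinedScoreError("correlation undefined for a zero-variance vector")
    return float(np.dot(ac, bc)) / (na * nb)


def ccr(y, mx, mb) -> float:
    """Ratio of Pearson correlations CC(y, x) / CC(y, b).

    When CC(y, b) is exactly zero the ratio is a signed-infinity sentinel,
    so the threshold (> 1 confirms) is decided by the sign of CC(y, x).
    """
    yv = _values(y)
    cc_x = _pearson(yv, _values(mx))
    cc_b = _pearson(yv, _values(mb))
    if cc_b == 0:
        return math.copysign(math.inf, cc_x) if cc_x != 0 else math.nan
    return cc_x / cc_b


def confirm(y, mx: ArrhythmiaModel, mb: ArrhythmiaModel) -> ConfirmationResult:
    """Run all three confirmation functions and combine them with AND.

    The continuous ``score`` is -LDSR (higher = more like the hypothesized
    class); it is the scalar swept to draw ROC curves, since the three
    fixed thresholds alone define a single operating point.
    """
    yv = _values(y)
    p_x = prds(yv, mx)
    p_b = prds(yv, mb)
    if p_b == 0 and p_x == 0:
        raise UndefinedScoreError("PRDS ratio undefined: y equals both models")
    ratio = math.inf if p_b == 0 else p_x / p_b
    ld = ldsr(yv, mx, mb)
    cc_x = _pearson(yv, _values(mx))
    cc_b = _pearson(yv, _values(mb))
    if cc_b == 0:
        cr = math.copysign(math.inf, cc_x) if cc_x != 0 else math.nan
    else:
        cr = cc_x / cc_b
    c_prds = ratio < 1.0
    c_ldsr = ld <= 0.0
    c_ccr = cr > 1.0
    return ConfirmationResult(
        prds_x=p_x,
        prds_b=p_b,
        prds_ratio=ratio,
        ldsr=ld,
        cc_x=cc_x,
        cc_b=cc_b,
        ccr=cr,
        confirm_prds=c_prds,
        confirm_ldsr=c_ldsr,
        confirm_ccr=c_ccr,
        confirmed=c_prds and c_ldsr and c_ccr,
        score=-ld,
    )


def save_model(model: ArrhythmiaModel, path: str | Path) -> None:
    """Serialize a model to JSON."""
    payload = {
        "class_label": model.class_label,
        "n_training": model.n_training,
        "extractor": model.extractor,
        "config": model.config.__dict__,
        "mean_vector": model.mean_vector.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_model(path: str | Path) -> ArrhythmiaModel:
    """Load a model saved by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    return ArrhythmiaModel(
        mean_vector=np.asarray(payload["mean_vector"], dtype=float),
        class_label=payload["class_label"],
        n_training=int(payload["n_training"]),
        config=WaveletConfig(**payload["config"]),
        extractor=payload.get("extractor", "WAFE"),
    )
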