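"""Scoring of confirmation decisions: confusion counts, recognition rate,
ROC/AUC, and the end-to-end benchmark harness (with optional noise injection).

Recognition rate is the arithmetic mean of sensitivity, specificity and
positive predictivity, each in percent. The ROC sweeps the continuous
confirmation score (-LDSR); the three-way AND rule itself yields only a
single operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .confirmation import ArrhythmiaModel, ConfirmationResult, build_model, confirm
from .exceptions import IncompatibleFeaturesError, UndefinedMeasureError
from .features import WaveletConfig, extract_features
from .io import ECGSegment, PreprocessConfig, add_awgn, preprocess

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "ROCCurve",
    "tally",
    "metrics",
    "roc",
    "run_benchmark",
    "BenchmarkResult",
]


@dataclass
class ConfusionCounts:
    """2x2 confusion counts; positive = confirmed as the hypothesized class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise UndefinedMeasureError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalReport:
    """Sensitivity / specificity / positive predictivity (percent) and their mean."""

    sensitivity: float
    specificity: float
    positive_predictivity: float
    recognition_rate: float
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "positive_predictivity": self.positive_predictivity,
            "recognition_rate": self.recognition_rate,
            "counts": {
                "tp": self.counts.tp,
                "tn": self.counts.tn,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
            },
        }


@dataclass
class ROCCurve:
    """A threshold sweep of TPR against FPR with its trapezoidal area."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def tally(decisions, labels) -> ConfusionCounts:
    """Count TP/TN/FP/FN from boolean decisions vs boolean is-target labels."""
    d = np.asarray(decisions, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if d.shape != y.shape:
        raise IncompatibleFeaturesError(f"shape mismatch {d.shape} vs {y.shape}")
    return ConfusionCounts(
        tp=int(np.sum(d & y)),
        tn=int(np.sum(~d & ~y)),
        fp=int(np.sum(d & ~y)),
        fn=int(np.sum(~d & y)),
    )


def metrics(counts: ConfusionCounts) -> EvalReport:
    """Sensitivity, specificity, positive predictivity and recognition rate.

    sensitivity = TP/(TP+FN)*100, specificity = TN/(TN+FP)*100,
    positive predictivity = TP/(TP+FP)*100; recognition rate is their mean.
    """
    if counts.tp + counts.fn == 0:
        raise UndefinedMeasureError("sensitivity undefined: TP + FN = 0")
    if counts.tn + counts.fp == 0:
        raise UndefinedMeasureError("specificity undefined: TN + FP = 0")
    if counts.tp + counts.fp == 0:
        raise UndefinedMeasureError("positive predictivity undefined: TP + FP = 0")
    sens = 100.0 * counts.tp / (counts.tp + counts.fn)
    spec = 100.0 * counts.tn / (counts.tn + counts.fp)
    ppv = 100.0 * counts.tp / (counts.tp + counts.fp)
    return EvalReport(
        sensitivity=sens,
        specificity=spec,
        positive_predictivity=ppv,
        recognition_rate=(sens + spec + ppv) / 3.0,
        counts=counts,
    )


def roc(scores, labels) -> ROCCurve:
    """ROC curve over all distinct score thresholds; AUC by trapezoid rule."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if not y.any() or y.all():
        raise UndefinedMeasureError("ROC needs both positive and negative labels")
    fpr, tpr, thr = _sk_roc_curve(y.astype(int), s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


@dataclass
class BenchmarkResult:
    """Everything one benchmark run produced."""

    report: EvalReport
    roc: ROCCurve
    results: list[ConfirmationResult] = field(repr=False)
    labels: np.ndarray = field(repr=False)
    chf_model: ArrhythmiaModel = field(repr=False)
    background_model: ArrhythmiaModel = field(repr=False)


def run_benchmark(
    chf_segments: list[ECGSegment],
    background_segments: list[ECGSegment],
    wavelet_cfg: WaveletConfig | None = None,
    pre_cfg: PreprocessConfig | None = None,
    extractor: str = "WAFE",
    snr_db: float | None = None,
    seed: int = 0,
    n_model: int = 15,
) -> BenchmarkResult:
    """Model-build + confirm + score a CHF-vs-background experiment.

    The first ``n_model`` raw segments of each class are used (clean) to
    build the hypothesized and background models and are excluded from
    testing. Remaining segments are test items; when ``snr_db`` is given,
    white Gaussian noise at that SNR is injected into each raw test segment
    (with a per-segment seed derived from ``seed``) before preprocessing.
    Fully reproducible for a fixed seed.
    """
    wavelet_cfg = wavelet_cfg or WaveletConfig()
    pre_cfg = pre_cfg or PreprocessConfig()
    if len(chf_segments) <= n_model or len(background_segments) <= n_model:
        raise IncompatibleFeaturesError(
            f"need more than {n_model} segments per class (model building + >= 1 test)"
        )

    def _features(seg: ECGSegment):
        return extract_features(preprocess(seg, pre_cfg), wavelet_cfg, extractor)

    chf_model = build_model([_features(s) for s in chf_segments[:n_model]], "CHF")
    bg_label = background_segments[0].label
    bg_model = build_model([_features(s) for s in background_segments[:n_model]], bg_label)

    test = [(s, True) for s in chf_segments[n_model:]]
    test += [(s, False) for s in background_segments[n_model:]]
    noise_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=len(test))

    results: list[ConfirmationResult] = []
    labels = np.empty(len(test), dtype=bool)
    for i, (seg, is_chf) in enumerate(test):
        if snr_db is not None:
            seg = add_awgn(seg, snr_db, seed=int(noise_seeds[i]))
        results.append(confirm(_features(seg), chf_model, bg_model))
        labels[i] = is_chf

    decisions = [r.confirmed for r in results]
    counts = tally(decisions, labels)
    if counts.tp + counts.fp == 0:
        # the detector confirmed nothing (possible under heavy noise):
        # positive predictivity is 0/0; score it 0% — the most pessimistic
        # value — so degradation studies remain well defined
        sens = 100.0 * counts.tp / (counts.tp + counts.fn)
        spec = 100.0 * counts.tn / (counts.tn + counts.fp)
        report = EvalReport(sens, spec, 0.0, (sens + spec) / 3.0, counts)
    else:
        report = metrics(counts)
    curve = roc([r.score for r in results], labels)
    return BenchmarkResult(report, curve, results, labels, chf_model, bg_model)
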