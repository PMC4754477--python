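"""Wavelet-packet subband features for ECG rhythm characterization.

The primary extractor is WAFE (wavelet average-framing percentage energy):
the segment is decomposed into the 2**level terminal subbands of a
wavelet-packet tree, each terminal node is reconstructed to a full-length
subsignal, each subsignal is cut into Z equal frames, the per-frame
percentage energies across nodes are computed (they sum to 100 within each
frame), and the Z frame vectors are averaged. The result is a length-2**level
vector in percent that captures how the segment's energy is distributed over
frequency subbands — the signature that differs between rhythm classes.

Comparison extractors over the same tree: per-node Shannon, log-energy and
SURE entropies of the coefficient blocks, and the per-node mean Welch power
spectral density.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json
import math

import numpy as np
import pywt
from scipy import signal as sps

from .exceptions import DecompositionError, DegenerateSignalError, IncompatibleFeaturesError
from .io import ECGSegment

__all__ = [
    "WaveletConfig",
    "WPTerminalSubsignals",
    "FeatureVector",
    "FeatureStatistics",
    "wpt_decompose",
    "percentage_energy",
    "extract_afe",
    "extract_entropy_features",
    "extract_wpap",
    "extract_features",
    "feature_statistics",
    "features_to_csv",
    "features_from_csv",
    "EXTRACTORS",
]

_LOG_GUARD = 1e-12


@dataclass(frozen=True)
class WaveletConfig:
    """Wavelet-packet decomposition and framing settings.

    Parameters
    ----------
    wavelet_name : str
        Mother wavelet (default ``"db5"``, Daubechies order 5).
    level : int
        Decomposition depth L; the tree has Q = 2**L terminal nodes.
    n_frames : int
        Z, the number of equal non-overlapping frames per subsignal that
        percentage energies are averaged over. The default Z=5 gives 2 s
        frames on a 10 s segment, i.e. roughly 2-3 beats per frame.
    node_order : str
        ``"natural"`` (filter-bank) or ``"frequency"`` terminal-node order.
        Ordering only permutes the feature vector; it must be the same for
        every vector that is compared.
    boundary_mode : str
        Signal-extension mode of the filter bank. ``"periodization"`` makes
        the orthonormal transform energy-preserving, which the percentage
        semantics rely on.
    """

    wavelet_name: str = "db5"
    level: int = 5
    n_frames: int = 5
    node_order: str = "natural"
    boundary_mode: str = "periodization"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise DecompositionError("level must be >= 1")
        if self.n_frames < 1:
            raise DecompositionError("n_frames must be >= 1")
        if self.node_order not in ("natural", "frequency"):
            raise DecompositionError(f"unknown node_order {self.node_order!r}")

    @property
    def n_nodes(self) -> int:
        """Q, the number of terminal subbands."""
        return 2**self.level


@dataclass
class WPTerminalSubsignals:
    """Terminal-node content of a level-L wavelet-packet tree.

    ``subsignals`` holds the Q full-length reconstructions u_q(t) (one row
    per node, length = analyzed signal length); ``coefficients`` the raw
    terminal coefficient blocks; ``total_energy`` the energy of the whole
    decomposition vector C (equal to the analyzed signal's energy for an
    orthonormal wavelet with periodization).
    """

    subsignals: np.ndarray
    coefficients: list[np.ndarray]
    node_paths: list[str]
    total_energy: float
    config: WaveletConfig
    fs: float

    @property
    def n_nodes(self) -> int:
        return self.subsignals.shape[0]

    @property
    def length(self) -> int:
        return self.subsignals.shape[1]


@dataclass
class FeatureVector:
    """A length-Q subband feature vector with extraction metadata."""

    values: np.ndarray
    extractor: str
    config: WaveletConfig
    source_id: str = ""
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise IncompatibleFeaturesError("feature values must be one-dimensional")


@dataclass
class FeatureStatistics:
    """Descriptive statistics over the Q entries of one feature vector."""

    std: float
    median: float
    max: float
    var: float


def _reconstruct_node(path: str, coeffs: np.ndarray, wavelet: str, mode: str) -> np.ndarray:
    """Upsample one terminal node back to signal length through the inverse
    filter bank, with all sibling nodes zeroed."""
    rec = coeffs
    for ch in reversed(path):
        if ch == "a":
            rec = pywt.idwt(rec, None, wavelet, mode)
        else:
            rec = pywt.idwt(None, rec, wavelet, mode)
    return rec


def wpt_decompose(seg: ECGSegment, cfg: WaveletConfig | None = None) -> WPTerminalSubsignals:
    """Decompose a segment into its level-L terminal subband subsignals.

    The transform analyzes the largest prefix whose length is divisible by
    2**level (a 2500-sample segment is analyzed over its first 2496
    samples); this keeps the periodized orthonormal filter bank exactly
    energy-preserving and perfectly reconstructing, which the percentage
    semantics and their tests rely on. The trailing few samples (at most
    2**level - 1, i.e. <= 124 ms at 250 Hz / level 5) are discarded, the
    same policy framing applies to remainder samples.
    """
    cfg = cfg or WaveletConfig()
    block = 2**cfg.level
    n = (seg.n_samples // block) * block
    if n == 0:
        raise DecompositionError(
            f"segment of {seg.n_samples} samples is shorter than 2^level = {block}"
        )
    x = seg.samples[:n]
    wp = pywt.WaveletPacket(x, cfg.wavelet_name, mode=cfg.boundary_mode, maxlevel=cfg.level)
    order = "freq" if cfg.node_order == "frequency" else "natural"
    nodes = wp.get_level(cfg.level, order=order)
    coeffs = [np.asarray(nd.data, dtype=np.float64) for nd in nodes]
    paths = [nd.path for nd in nodes]
    total_energy = float(sum(np.sum(c**2) for c in coeffs))
    subs = np.empty((len(nodes), n))
    for i, (p, c) in enumerate(zip(paths, coeffs)):
        subs[i] = _reconstruct_node(p, c, cfg.wavelet_name, cfg.boundary_mode)[:n]
    return WPTerminalSubsignals(
        subsignals=subs,
        coefficients=coeffs,
        node_paths=paths,
        total_energy=total_energy,
        config=cfg,
        fs=seg.fs,
    )


def _frame_bounds(length: int, z: int, n_frames: int) -> tuple[int, int]:
    flen = length // n_frames
    if flen == 0:
        raise DecompositionError(
            f"cannot cut a length-{length} subsignal into {n_frames} frames"
        )
    return (z - 1) * flen, z * flen


def percentage_energy(subsignals: WPTerminalSubsignals, frame_index: int) -> np.ndarray:
    """Per-node percentage energy of one frame.

    Entry q is 100 * energy(frame z of u_q) / sum over nodes of the same
    frame's energy, so the vector sums to 100 for every non-degenerate
    frame. ``frame_index`` is 1-based (z = 1..Z).
    """
    z = frame_index
    Z = subsignals.config.n_frames
    if not 1 <= z <= Z:
        raise DecompositionError(f"frame_index must be in 1..{Z}, got {z}")
    lo, hi = _frame_bounds(subsignals.length, z, Z)
    energies = np.sum(subsignals.subsignals[:, lo:hi] ** 2, axis=1)
    total = energies.sum()
    if total == 0:
        raise DegenerateSignalError(f"frame {z} carries no energy in any node")
    return 100.0 * energies / total


def extract_afe(seg: ECGSegment, cfg: WaveletConfig | None = None) -> FeatureVector:
    """WAFE: average-framing percentage-energy feature vector.

    afe_q = (1/Z) * sum over z of the percentage energy of node q in frame
    z. Each frame vector sums to 100, so the average does too. Percentage
    energies are ratios of quadratic forms, making the feature invariant to
    global amplitude scaling.
    """
    cfg = cfg or WaveletConfig()
    subs = wpt_decompose(seg, cfg)
    acc = np.zeros(subs.n_nodes)
    for z in range(1, cfg.n_frames + 1):
        acc += percentage_energy(subs, z)
    return FeatureVector(acc / cfg.n_frames, "WAFE", cfg, seg.source_id, seg.label)


def _shannon_entropy(c: np.ndarray) -> float:
    e = c**2
    total = e.sum()
    if total == 0:
        return 0.0
    p = e / total
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def _log_energy_entropy(c: np.ndarray) -> float:
    return float(np.sum(np.log(np.maximum(c**2, _LOG_GUARD))))


def _sure_entropy(c: np.ndarray) -> float:
    n = len(c)
    arg = max(n * math.log2(max(n, 2)), 1.0)
    tau2 = 2.0 * math.log(arg)
    return float(np.sum(np.minimum(c**2, tau2)))


_ENTROPY_FUNCS = {
    "shannon": _shannon_entropy,
    "log_energy": _log_energy_entropy,
    "sure": _sure_entropy,
}

_ENTROPY_NAMES = {"shannon": "WPSE", "log_energy": "WPLE", "sure": "WPSUE"}


def extract_entropy_features(
    seg: ECGSegment, cfg: WaveletConfig | None = None, kind: str = "shannon"
) -> FeatureVector:
    """Per-node wavelet-packet entropy features (WPSE / WPLE / WPSUE).

    For each terminal node the entropy of its coefficient block is computed
    per frame (the block is cut into Z equal windows, remainder dropped) and
    averaged over frames, mirroring the WAFE framing. Definitions are the
    standard wavelet-toolbox ones: Shannon entropy of the normalized squared
    coefficients (0*log0 := 0); log-energy entropy sum(log c_i^2) with a
    1e-12 guard; SURE entropy sum(min(c_i^2, tau^2)) with
    tau = sqrt(2*log(n*log2(n))).
    """
    cfg = cfg or WaveletConfig()
    if kind not in _ENTROPY_FUNCS:
        raise IncompatibleFeaturesError(f"unknown entropy kind {kind!r}")
    func = _ENTROPY_FUNCS[kind]
    subs = wpt_decompose(seg, cfg)
    Z = cfg.n_frames
    out = np.empty(subs.n_nodes)
    for q, c in enumerate(subs.coefficients):
        flen = len(c) // Z
        if flen == 0:
            raise DecompositionError(
                f"coefficient block of {len(c)} values cannot form {Z} frames"
            )
        out[q] = np.mean([func(c[z * flen : (z + 1) * flen]) for z in range(Z)])
    return FeatureVector(out, _ENTROPY_NAMES[kind], cfg, seg.source_id, seg.label)


def extract_wpap(seg: ECGSegment, cfg: WaveletConfig | None = None) -> FeatureVector:
    """Per-node average power spectral density (WPAP).

    For each terminal subsignal, each of the Z frames is Welch-estimated
    (Hann window, 256-sample segments or the frame length if shorter, 50%
    overlap) and the mean PSD value is taken; frame means are averaged.
    """
    cfg = cfg or WaveletConfig()
    subs = wpt_decompose(seg, cfg)
    if subs.total_energy == 0:
        raise DegenerateSignalError("zero signal has no power spectrum")
    Z = cfg.n_frames
    lo0, hi0 = _frame_bounds(subs.length, 1, Z)
    flen = hi0 - lo0
    nperseg = min(256, flen)
    out = np.empty(subs.n_nodes)
    for q in range(subs.n_nodes):
        vals = []
        for z in range(1, Z + 1):
            lo, hi = _frame_bounds(subs.length, z, Z)
            _f, pxx = sps.welch(
                subs.subsignals[q, lo:hi],
                fs=subs.fs,
                window="hann",
                nperseg=nperseg,
                noverlap=nperseg // 2,
            )
            vals.append(np.mean(pxx))
        out[q] = np.mean(vals)
    return FeatureVector(out, "WPAP", cfg, seg.source_id, seg.label)


EXTRACTORS = {
    "WAFE": extract_afe,
    "WPSE": lambda seg, cfg=None: extract_entropy_features(seg, cfg, "shannon"),
    "WPLE": lambda seg, cfg=None: extract_entropy_features(seg, cfg, "log_energy"),
    "WPSUE": lambda seg, cfg=None: extract_entropy_features(seg, cfg, "sure"),
    "WPAP": extract_wpap,
}


def extract_features(seg: ECGSegment, cfg: WaveletConfig | None = None, extractor: str = "WAFE") -> FeatureVector:
    """Dispatch to one of the named extractors (WAFE, WPSE, WPLE, WPSUE, WPAP)."""
    try:
        func = EXTRACTORS[extractor.upper()]
    except KeyError:
        raise IncompatibleFeaturesError(
            f"unknown extractor {extractor!r}; choose from {sorted(EXTRACTORS)}"
        ) from None
    return func(seg, cfg)


def feature_statistics(fv: FeatureVector) -> FeatureStatistics:
    """Population std / median / max / variance over the vector's entries."""
    v = fv.values
    return FeatureStatistics(
        std=float(np.std(v)),
        median=float(np.median(v)),
        max=float(np.max(v)),
        var=float(np.var(v)),
    )


def features_to_csv(features: list[FeatureVector], path: str | Path) -> None:
    """Write feature vectors to CSV (one row per segment) plus a JSON
    sidecar ``<path>.json`` carrying the shared WaveletConfig."""
    import pandas as pd

    if not features:
        raise IncompatibleFeaturesError("no feature vectors to write")
    cfg = features[0].config
    q = cfg.n_nodes
    rows = []
    for fv in features:
        if fv.config != cfg:
            raise IncompatibleFeaturesError("feature vectors carry different configs")
        rows.append([fv.source_id, fv.label, fv.extractor, *fv.values])
    cols = ["source_id", "label", "extractor"] + [f"v{i + 1}" for i in range(q)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.17g")
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps(cfg.__dict__, indent=2) + "\n")


def features_from_csv(path: str | Path) -> list[FeatureVector]:
    """Read feature vectors written by :func:`features_to_csv`."""
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        cfg = WaveletConfig(**json.loads(sidecar.read_text()))
    else:
        cfg = WaveletConfig()
    vcols = [c for c in df.columns if c.startswith("v")]
    return [
        FeatureVector(
            row[vcols].to_numpy(dtype=float),
            extractor=row["extractor"],
            config=cfg,
            source_id=str(row["source_id"]),
            label=str(row["label"]),
        )
        for _, row in df.iterrows()
    ]
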