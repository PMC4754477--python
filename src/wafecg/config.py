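"""Run configuration and end-to-end pipeline orchestration.

A :class:`RunConfig` gathers every knob of the synthetic benchmark workflow
(generator, preprocessing, wavelet decomposition, extractor choice, noise,
seed) into one flat, file-round-trippable object. :func:`run_pipeline`
executes generate -> preprocess -> extract -> model -> confirm -> score and
writes ``report.json`` and ``roc.csv`` stamped with the config hash.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import math
from dataclasses import dataclass, asdict, fields
from pathlib import Path

from .evaluation import run_benchmark
from .exceptions import ConfigError
from .features import WaveletConfig, EXTRACTORS
from .io import PreprocessConfig
from .synthetic import PRESETS, synth_dataset

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Flat configuration of one benchmark run (all fields file-serializable)."""

    # generator
    chf_class: str = "CHF"
    background_class: str = "NSR"
    n_model: int = 15
    n_test: int = 150
    duration_s: float = 10.0
    fs: float = 250.0
    # preprocessing
    target_fs: float = 250.0
    hp_cutoff: float = 0.5
    lp_cutoff: float = 40.0
    filter_order: int = 4
    normalize: bool = True
    # features
    wavelet: str = "db5"
    level: int = 5
    n_frames: int = 5
    node_order: str = "natural"
    extractor: str = "WAFE"
    # experiment
    snr_db: float = math.inf  # inf = no injected noise
    seed: int = 1
    out_dir: str = "wafecg_out"
    log_level: str = "INFO"

    def validate(self) -> None:
        """Raise ConfigError listing every invalid field at once."""
        problems = []
        if self.chf_class not in PRESETS:
            problems.append(f"chf_class: unknown preset {self.chf_class!r}")
        if self.background_class not in PRESETS:
            problems.append(f"background_class: unknown preset {self.background_class!r}")
        if self.n_model < 1:
            problems.append("n_model: must be >= 1")
        if self.n_test < 1:
            problems.append("n_test: must be >= 1")
        if self.extractor.upper() not in EXTRACTORS:
            problems.append(f"extractor: unknown {self.extractor!r}")
        if not (0 < self.hp_cutoff < self.lp_cutoff < self.target_fs / 2):
            problems.append("hp_cutoff/lp_cutoff: need 0 < hp < lp < target_fs/2")
        if self.level < 1:
            problems.append("level: must be >= 1")
        if self.n_frames < 1:
            problems.append("n_frames: must be >= 1")
        if self.duration_s <= 0:
            problems.append("duration_s: must be positive")
        if self.fs <= 0:
            problems.append("fs: must be positive")
        if problems:
            raise ConfigError("invalid configuration: " + "; ".join(problems))

    def wavelet_config(self) -> WaveletConfig:
        return WaveletConfig(
            wavelet_name=self.wavelet,
            level=self.level,
            n_frames=self.n_frames,
            node_order=self.node_order,
        )

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(
            target_fs=self.target_fs,
            hp_cutoff=self.hp_cutoff,
            lp_cutoff=self.lp_cutoff,
            filter_order=self.filter_order,
            normalize=self.normalize,
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_file(self, path: str | Path) -> None:
        cp = configparser.ConfigParser()
        cp["run"] = {k: repr(v) if isinstance(v, str) else str(v) for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        cp = configparser.ConfigParser()
        if not cp.read(path):
            raise ConfigError(f"cannot read config file {path}")
        if "run" not in cp:
            raise ConfigError(f"{path}: missing [run] section")
        raw = dict(cp["run"])
        kwargs = {}
        for f in fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.type in ("int",):
                kwargs[f.name] = int(v)
            elif f.type in ("float",):
                kwargs[f.name] = float(v)
            elif f.type in ("bool",):
                kwargs[f.name] = v.strip().lower() in ("true", "1", "yes")
            else:
                kwargs[f.name] = v.strip("'\"")
        return cls(**kwargs)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic benchmark described by ``config``.

    Writes ``report.json`` (metrics, AUC, feature dimension, config hash)
    and ``roc.csv`` (threshold, fpr, tpr rows) into the output directory and
    returns the report dictionary.
    """
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    n_total = config.n_model + config.n_test
    chf = synth_dataset([PRESETS[config.chf_class]], n_total, config.duration_s, config.fs, seed=config.seed)
    bg = synth_dataset(
        [PRESETS[config.background_class]], n_total, config.duration_s, config.fs, seed=config.seed + 1
    )
    snr = None if math.isinf(config.snr_db) else config.snr_db
    bench = run_benchmark(
        chf,
        bg,
        wavelet_cfg=config.wavelet_config(),
        pre_cfg=config.preprocess_config(),
        extractor=config.extractor.upper(),
        snr_db=snr,
        seed=config.seed,
        n_model=config.n_model,
    )
    report = {
        "config_hash": config.config_hash(),
        "config": {k: (str(v) if isinstance(v, float) and math.isinf(v) else v) for k, v in asdict(config).items()},
        "feature_dimension": config.wavelet_config().n_nodes,
        "n_test_segments": int(bench.labels.size),
        **bench.report.as_dict(),
        "auc": bench.roc.auc,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    lines = ["threshold,fpr,tpr"]
    for thr, fp, tp in zip(bench.roc.thresholds, bench.roc.fpr, bench.roc.tpr):
        lines.append(f"{thr:.17g},{fp:.17g},{tp:.17g}")
    (out / "roc.csv").write_text("\n".join(lines) + "\n")
    return report
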