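"""Minimal reader/writer for PhysioNet WFDB records (.hea + .dat).

Supports the two storage formats that cover the MIT-BIH / BIDMC family:
format 212 (two 12-bit samples packed in 3 bytes) and format 16
(little-endian int16). Only single-segment records; samples are converted
to physical units as (digital - baseline) / gain.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import FormatError

__all__ = ["WFDBSignalSpec", "read_record", "write_record"]


@dataclass
class WFDBSignalSpec:
    """One signal line of a .hea header."""

    file_name: str
    fmt: int
    gain: float  # ADC units per physical unit (0 -> default 200)
    baseline: int  # ADC value mapping to 0 physical units
    units: str
    description: str  # lead name, e.g. "MLII", "V1", "ECG1"


_GAIN_RE = re.compile(
    r"^(?P<gain>[-+0-9.eE]+)?(?:\((?P<baseline>[-+0-9]+)\))?(?:/(?P<units>\S+))?$"
)


def _parse_signal_line(line: str, adc_zero_default: int = 0) -> WFDBSignalSpec:
    tok = line.split()
    if len(tok) < 2:
        raise FormatError(f"WFDB signal line too short: {line!r}")
    file_name = tok[0]
    fmt_field = tok[1].split("x")[0].split(":")[0].split("+")[0]
    try:
        fmt = int(fmt_field)
    except ValueError as exc:
        raise FormatError(f"WFDB signal line: bad format field {tok[1]!r}") from exc
    gain, baseline, units = 200.0, None, "mV"
    if len(tok) >= 3:
        m = _GAIN_RE.match(tok[2])
        if m is None:
            raise FormatError(f"WFDB signal line: bad gain field {tok[2]!r}")
        if m.group("gain"):
            gain = float(m.group("gain"))
        if m.group("baseline") is not None:
            baseline = int(m.group("baseline"))
        if m.group("units"):
            units = m.group("units")
    adc_zero = adc_zero_default
    if len(tok) >= 5:
        try:
            adc_zero = int(tok[4])
        except ValueError:
            pass
    if baseline is None:
        baseline = adc_zero
    if gain == 0:
        gain = 200.0
    description = " ".join(tok[8:]) if len(tok) > 8 else file_name
    return WFDBSignalSpec(file_name, fmt, gain, baseline, units, description)


def read_header(hea_path: str | Path) -> tuple[str, float, int, list[WFDBSignalSpec]]:
    """Parse a .hea file -> (record_name, fs, n_samples, signal specs)."""
    hea_path = Path(hea_path)
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"{hea_path}: empty WFDB header")
    head = lines[0].split()
    if len(head) < 2:
        raise FormatError(f"{hea_path}: record line too short: {lines[0]!r}")
    record_name = head[0].split("/")[0]
    try:
        n_sig = int(head[1])
    except ValueError as exc:
        raise FormatError(f"{hea_path}: bad signal count {head[1]!r}") from exc
    fs = 250.0
    if len(head) >= 3:
        try:
            fs = float(head[2].split("/")[0])
        except ValueError as exc:
            raise FormatError(f"{hea_path}: bad sampling frequency {head[2]!r}") from exc
    n_samples = 0
    if len(head) >= 4:
        try:
            n_samples = int(head[3])
        except ValueError as exc:
            raise FormatError(f"{hea_path}: bad sample count {head[3]!r}") from exc
    if len(lines) - 1 < n_sig:
        raise FormatError(f"{hea_path}: header declares {n_sig} signals, found {len(lines) - 1} lines")
    specs = [_parse_signal_line(ln) for ln in lines[1 : 1 + n_sig]]
    return record_name, fs, n_samples, specs


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    n_pairs = len(b) // 3
    b = b[: n_pairs * 3].reshape(-1, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * n_pairs, dtype=np.int32)
    out[0::2] = first
    out[1::2] = second
    out[out > 2047] -= 4096  # 12-bit two's complement
    return out[:n_values]


def read_record(hea_path: str | Path) -> tuple[float, dict[str, np.ndarray], dict[str, str]]:
    """Read a WFDB record.

    Returns (fs, {lead description: physical samples}, {lead: units}).
    """
    hea_path = Path(hea_path)
    record_name, fs, n_samples, specs = read_header(hea_path)
    fmts = {s.fmt for s in specs}
    if not fmts <= {16, 212}:
        raise FormatError(f"{hea_path}: unsupported WFDB format(s) {sorted(fmts - {16, 212})}")
    dat_files = {s.file_name for s in specs}
    if len(dat_files) != 1:
        raise FormatError(f"{hea_path}: multi-file records are not supported")
    dat_path = hea_path.parent / specs[0].file_name
    if not dat_path.exists():
        raise FormatError(f"{hea_path}: missing data file {specs[0].file_name!r}")
    raw = dat_path.read_bytes()
    n_sig = len(specs)
    fmt = specs[0].fmt
    if fmt == 212:
        total = n_samples * n_sig if n_samples else (len(raw) // 3) * 2
        digital = _decode_212(raw, total)
    else:
        digital = np.frombuffer(raw, dtype="<i2").astype(np.int32)
        if n_samples:
            digital = digital[: n_samples * n_sig]
    usable = (len(digital) // n_sig) * n_sig
    digital = digital[:usable].reshape(-1, n_sig)
    signals: dict[str, np.ndarray] = {}
    units: dict[str, str] = {}
    for i, s in enumerate(specs):
        signals[s.description] = (digital[:, i] - s.baseline) / s.gain
        units[s.description] = s.units
    return fs, signals, units


def write_record(
    hea_path: str | Path,
    fs: float,
    signals: dict[str, np.ndarray],
    gain: float = 200.0,
    units: str = "mV",
) -> None:
    """Write signals as a format-16 WFDB record (one .hea and one .dat file)."""
    hea_path = Path(hea_path)
    record_name = hea_path.stem
    dat_name = record_name + ".dat"
    leads = list(signals)
    lengths = {len(np.asarray(signals[ld])) for ld in leads}
    if len(lengths) != 1:
        raise FormatError("all leads must have the same length")
    n = lengths.pop()
    digital = np.empty((n, len(leads)), dtype="<i2")
    for i, ld in enumerate(leads):
        d = np.round(np.asarray(signals[ld], dtype=float) * gain)
        if np.any(~np.isfinite(d)):
            raise FormatError(f"lead {ld!r}: non-finite samples")
        digital[:, i] = np.clip(d, -32768, 32767).astype("<i2")
    lines = [f"{record_name} {len(leads)} {fs:g} {n}"]
    for ld in leads:
        lines.append(f"{dat_name} 16 {gain:g}(0)/{units} 16 0 0 0 0 {ld}")
    hea_path.write_text("\n".join(lines) + "\n")
    (hea_path.parent / dat_name).write_bytes(digital.tobytes())
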