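"""Plain-text jMRUI file reading and writing.

Implements the widespread ASCII dialect: a header block of ``Key: value``
lines (PointsInDataset, DatasetsInFile, SamplingInterval in ms,
TransmitterFrequency in Hz, ...), then per-signal sections introduced by
``Signal N out of M in file`` with tab-separated real/imaginary FID columns
(plus the corresponding spectrum columns). Binary jMRUI and vendor raw
formats are not supported.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import Fid, SpectralAxis

__all__ = ["JmruiFormatError", "write_jmrui", "read_jmrui"]

MANDATORY_KEYS = ("PointsInDataset", "DatasetsInFile", "SamplingInterval", "TransmitterFrequency")


class JmruiFormatError(ValueError):
    """The file does not parse as plain-text jMRUI."""


def write_jmrui(
    signals: Sequence[np.ndarray],
    axis: SpectralAxis,
    path,
    names: Optional[Sequence[str]] = None,
    extra_header: Optional[Dict[str, str]] = None,
) -> None:
    """Write complex signals as one plain-text jMRUI document.

    Samples are printed with 9 significant digits; SamplingInterval is in
    ms and TransmitterFrequency in Hz, per the format's convention.
    """
    signals = [np.asarray(s, dtype=np.complex128) for s in signals]
    if not signals:
        raise ValueError("no signals to write")
    for s in signals:
        if s.ndim != 1 or len(s) == 0:
            raise ValueError("signals must be non-empty 1-D arrays")
        if len(s) != axis.n_points:
            raise ValueError("signal length does not match axis")
    names = list(names) if names is not None else [f"signal_{i}" for i in range(len(signals))]

    lines: List[str] = []
    lines.append("jMRUI Data Textfile")
    lines.append("")
    lines.append(f"Filename: {Path(path).name}")
    lines.append("")
    lines.append(f"PointsInDataset: {axis.n_points}")
    lines.append(f"DatasetsInFile: {len(signals)}")
    lines.append(f"SamplingInterval: {axis.dwell_time * 1e3:.9g}")
    lines.append("ZeroOrderPhase: 0E0")
    lines.append("BeginTime: 0E0")
    lines.append(f"TransmitterFrequency: {axis.transmitter_frequency * 1e6:.9g}")
    lines.append("MagneticField: 7E0")
    lines.append("TypeOfNucleus: 1E0")
    lines.append("NameOfPatient: ")
    lines.append("DateOfExperiment: ")
    lines.append("Spectrometer: ")
    lines.append("AdditionalInfo: ")
    lines.append(f"SignalNames: {';'.join(names)}")
    if extra_header:
        for k, v in extra_header.items():
            lines.append(f"{k}: {v}")
    lines.append("")
    lines.append("")
    lines.append("Signal and FFT")
    lines.append("sig(real)\tsig(imag)\tfft(real)\tfft(imag)")
    for i, s in enumerate(signals):
        spec = np.fft.fft(s)
        lines.append(f"Signal {i + 1} out of {len(signals)} in file")
        for k in range(len(s)):
            lines.append(
                f"{s[k].real:.9g}\t{s[k].imag:.9g}\t{spec[k].real:.9g}\t{spec[k].imag:.9g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_jmrui(path) -> Tuple[List[np.ndarray], SpectralAxis]:
    """Read a plain-text jMRUI document back into signals and an axis.

    The SpectralAxis is reconstructed from SamplingInterval (ms) and
    TransmitterFrequency (Hz); the carrier reference ppm is the package
    default (water at 4.7 ppm) as the format does not store it.
    """
    text = Path(path).read_text()
    header: Dict[str, str] = {}
    lines = text.splitlines()
    data_start = None
    for i, line in enumerate(lines):
        if line.startswith("Signal 1 out of"):
            data_start = i
            break
        if ":" in line:
            key, _, val = line.partition(":")
            header[key.strip()] = val.strip()
    if data_start is None:
        raise JmruiFormatError("no signal sections found")
    for key in MANDATORY_KEYS:
        if key not in header:
            raise JmruiFormatError(f"missing mandatory header key: {key}")
    n_points = int(float(header["PointsInDataset"]))
    n_sets = int(float(header["DatasetsInFile"]))
    dwell = float(header["SamplingInterval"]) * 1e-3
    tf_mhz = float(header["TransmitterFrequency"]) * 1e-6
    if dwell <= 0:
        raise JmruiFormatError("SamplingInterval must be positive")
    axis = SpectralAxis(n_points=n_points, dwell_time=dwell, transmitter_frequency=tf_mhz)

    signals: List[np.ndarray] = []
    current: List[complex] = []
    for line in lines[data_start:]:
        line = line.strip()
        if not line:
            continue
        if line.startswith("Signal ") and "out of" in line:
            if current:
                signals.append(np.asarray(current))
                current = []
            continue
        parts = line.split()
        if len(parts) < 2:
            raise JmruiFormatError(f"malformed data row: {line!r}")
        current.append(complex(float(parts[0]), float(parts[1])))
    if current:
        signals.append(np.asarray(current))
    if len(signals) != n_sets:
        raise JmruiFormatError(
            f"DatasetsInFile={n_sets} but found {len(signals)} signal sections"
        )
    for s in signals:
        if len(s) != n_points:
            raise JmruiFormatError("signal length does not match PointsInDataset")
    return signals, axis
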