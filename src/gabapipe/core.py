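"""Shared domain types and sequence-parameter arithmetic for edited MRS.

Conventions used throughout the package:

* The complex FID sample ``k`` sits at time ``t = k * dwell_time`` (sample 0
  is t=0, i.e. the echo top after localization).
* Chemical shift is referenced to the water carrier: a resonance at chemical
  shift ``delta`` (ppm) appears at the frequency offset
  ``(reference_ppm - delta) * transmitter_frequency`` Hz, so ppm increases
  with decreasing frequency offset (standard MRS display).
* Spectra returned by :meth:`Fid.spectrum` are ordered to match
  :attr:`SpectralAxis.ppm_axis`, which is strictly ascending in ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "InvalidAxisError",
    "InvalidProtocolError",
    "SpectralAxis",
    "Fid",
    "TransientSet",
    "SequenceProtocol",
    "hz_to_ppm",
    "ppm_to_hz",
    "chemical_shift_displacement",
    "acquisition_duration",
    "editing_symmetry_center",
]

WATER_PPM = 4.7
#: 7 T proton frequency (MHz) of the Siemens Magnetom platform.
DEFAULT_TRANSMITTER_MHZ = 297.2


class InvalidAxisError(ValueError):
    """A SpectralAxis violates its invariants."""


class InvalidProtocolError(ValueError):
    """A SequenceProtocol violates its invariants."""


@dataclass(frozen=True)
class SpectralAxis:
    """Time/frequency/ppm coordinate system of one acquisition.

    Parameters
    ----------
    n_points
        Number of complex FID samples (>= 64).
    dwell_time
        Sampling interval in seconds; spectral width = 1/dwell_time.
    transmitter_frequency
        Carrier frequency in MHz (default: 7 T proton frequency).
    reference_ppm
        Chemical shift assigned to the carrier (water, 4.7 ppm).
    """

    n_points: int = 4096
    dwell_time: float = 1.0 / 4000.0
    transmitter_frequency: float = DEFAULT_TRANSMITTER_MHZ
    reference_ppm: float = WATER_PPM

    def __post_init__(self) -> None:
        if self.n_points < 64:
            raise InvalidAxisError(f"n_points must be >= 64, got {self.n_points}")
        if not self.dwell_time > 0:
            raise InvalidAxisError("dwell_time must be positive")
        if not self.transmitter_frequency > 0:
            raise InvalidAxisError("transmitter_frequency must be positive")

    @property
    def spectral_width(self) -> float:
        """Spectral width in Hz."""
        return 1.0 / self.dwell_time

    @property
    def time_axis(self) -> np.ndarray:
        """Sample times in seconds, t[k] = k * dwell_time."""
        return np.arange(self.n_points) * self.dwell_time

    @property
    def frequency_axis(self) -> np.ndarray:
        """Frequency offsets in Hz, ascending (fftshift order)."""
        return np.fft.fftshift(np.fft.fftfreq(self.n_points, self.dwell_time))

    @property
    def ppm_axis(self) -> np.ndarray:
        """Chemical-shift axis in ppm, strictly ascending."""
        return (self.reference_ppm - self.frequency_axis / self.transmitter_frequency)[::-1]

    def frequency_of_ppm(self, ppm: float) -> float:
        """Frequency offset (Hz) of a resonance at chemical shift ``ppm``."""
        return (self.reference_ppm - ppm) * self.transmitter_frequency

    def ppm_of_frequency(self, hz: float) -> float:
        """Chemical shift (ppm) of a frequency offset ``hz``."""
        return self.reference_ppm - hz / self.transmitter_frequency


@dataclass
class Fid:
    """One complex free induction decay bound to a :class:`SpectralAxis`."""

    samples: np.ndarray
    axis: SpectralAxis

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.ndim != 1 or len(self.samples) != self.axis.n_points:
            raise ValueError(
                f"FID length {self.samples.shape} does not match axis "
                f"n_points={self.axis.n_points}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("FID contains non-finite samples")

    def spectrum(self) -> np.ndarray:
        """Complex spectrum ordered to match ``axis.ppm_axis`` (ascending ppm)."""
        return np.fft.fftshift(np.fft.fft(self.samples))[::-1]

    def with_samples(self, samples: np.ndarray) -> "Fid":
        return Fid(samples=samples, axis=self.axis)

    def __add__(self, other: "Fid") -> "Fid":
        self._check_axis(other)
        return Fid(self.samples + other.samples, self.axis)

    def __sub__(self, other: "Fid") -> "Fid":
        self._check_axis(other)
        return Fid(self.samples - other.samples, self.axis)

    def __mul__(self, scalar: complex) -> "Fid":
        return Fid(self.samples * scalar, self.axis)

    __rmul__ = __mul__

    def _check_axis(self, other: "Fid") -> None:
        if other.axis != self.axis:
            raise ValueError("Fids are bound to different axes")


EDIT_STATES = ("on", "off", "water_reference")


@dataclass
class TransientSet:
    """Raw unit of one measurement: per-coil, per-transient complex FIDs.

    ``data`` has shape ``(n_coils, n_transients, n_points)``; ``edit_states``
    labels each transient as ``on``, ``off`` or ``water_reference``. Dummy
    excitations are never materialized.
    """

    data: np.ndarray
    edit_states: tuple
    axis: SpectralAxis
    subject_id: str = "S00"
    measurement_index: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        self.edit_states = tuple(self.edit_states)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_coils, n_transients, n_points)")
        if self.data.shape[1] != len(self.edit_states):
            raise ValueError("edit_states length must match transient count")
        if self.data.shape[2] != self.axis.n_points:
            raise ValueError("sample count must match axis n_points")
        unknown = set(self.edit_states) - set(EDIT_STATES)
        if unknown:
            raise ValueError(f"unknown edit states: {unknown}")
        if len(self.water_indices) < 1:
            raise ValueError("at least one water_reference transient is required")
        if len(self.on_indices) != len(self.off_indices):
            raise ValueError(
                f"on/off transient counts differ: "
                f"{len(self.on_indices)} vs {len(self.off_indices)}"
            )
        if not self.measurement_index >= 1:
            raise ValueError("measurement_index is 1-based")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def n_transients(self) -> int:
        return self.data.shape[1]

    def _indices(self, state: str) -> tuple:
        return tuple(i for i, s in enumerate(self.edit_states) if s == state)

    @property
    def on_indices(self) -> tuple:
        return self._indices("on")

    @property
    def off_indices(self) -> tuple:
        return self._indices("off")

    @property
    def water_indices(self) -> tuple:
        return self._indices("water_reference")

    def fid(self, coil: int, transient: int) -> Fid:
        return Fid(self.data[coil, transient], self.axis)

    def water_fid(self, coil: int = 0) -> Fid:
        """First water-reference transient of the given coil."""
        return self.fid(coil, self.water_indices[0])


@dataclass(frozen=True)
class SequenceProtocol:
    """Acquisition parameters of the MEGA-sLASER protocol.

    Defaults reproduce the study protocol: TR 7 s (SAR limited), TE 74 ms,
    one water reference + 4 dummies + 32 edit-on + 32 edit-off, asymmetric
    excitation at 3.3 kHz, GOIA-WURST refocusing at 16.8 kHz, editing pulses
    at 1.9 (on) / 7.5 (off) ppm, 2x2x5 cm hippocampus voxel.
    """

    tr: float = 7.0
    te: float = 0.074
    n_water_ref: int = 1
    n_dummy: int = 4
    n_on: int = 32
    n_off: int = 32
    excitation_bandwidth: float = 3.3  # kHz
    refocusing_bandwidth: float = 16.8  # kHz
    editing_on_ppm: float = 1.9
    editing_off_ppm: float = 7.5
    voxel_dimensions: tuple = (2.0, 2.0, 5.0)  # cm

    def __post_init__(self) -> None:
        for name in ("n_water_ref", "n_dummy", "n_on", "n_off"):
            if getattr(self, name) < 0:
                raise InvalidProtocolError(f"{name} must be >= 0")
        if not (self.excitation_bandwidth > 0 and self.refocusing_bandwidth > 0):
            raise InvalidProtocolError("bandwidths must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in ml (product of cm dimensions)."""
        return float(np.prod(self.voxel_dimensions))


def hz_to_ppm(width_hz: float, axis: SpectralAxis) -> float:
    """Convert a width/offset in Hz to ppm on the given axis."""
    if width_hz < 0:
        raise ValueError("width must be non-negative")
    return width_hz / axis.transmitter_frequency


def ppm_to_hz(width_ppm: float, axis: SpectralAxis) -> float:
    """Exact inverse of :func:`hz_to_ppm`."""
    if width_ppm < 0:
        raise ValueError("width must be non-negative")
    return width_ppm * axis.transmitter_frequency


def chemical_shift_displacement(
    bandwidth_khz: float, span_ppm: float, axis: SpectralAxis
) -> float:
    """Fractional voxel displacement between two resonances ``span_ppm`` apart.

    For a selective pulse of the given bandwidth, the selected slab shifts by
    ``span_ppm * transmitter_frequency / bandwidth`` of the slab width between
    the two resonances (chemical shift displacement error, CSDE).
    """
    if not bandwidth_khz > 0:
        raise InvalidProtocolError("bandwidth must be positive")
    if span_ppm < 0:
        raise ValueError("span must be non-negative")
    return span_ppm * axis.transmitter_frequency / (bandwidth_khz * 1000.0)


def acquisition_duration(protocol: SequenceProtocol) -> float:
    """Total scan time in seconds: TR x (water + dummy + on + off)."""
    n = protocol.n_water_ref + protocol.n_dummy + protocol.n_on + protocol.n_off
    return protocol.tr * n


def editing_symmetry_center(on_ppm: float, off_ppm: float) -> float:
    """Midpoint of the two editing frequencies.

    The dual-band editing pulses are placed symmetrically around water, so the
    midpoint should equal the water reference ppm; used as a protocol sanity
    check.
    """
    if not (np.isfinite(on_ppm) and np.isfinite(off_ppm)):
        raise ValueError("editing frequencies must be finite")
    return 0.5 * (on_ppm + off_ppm)
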