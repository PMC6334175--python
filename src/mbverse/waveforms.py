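"""Shared waveform containers, hardware limits and pulse file I/O.

Unit conventions used throughout the package
--------------------------------------------
time        ms          (sample interval ``dt`` is in ms)
B1          µT          (complex RF samples)
gradient    mT/m
position    mm          (note: mT/m x mm = µT, so G*z adds directly to B1-scale
                         off-resonance terms)
frequency   kHz
k           rad/mm

The proton gyromagnetic ratio is ``GAMMA_BAR`` = 42.577e-3 kHz/µT
(equivalently 42.577 kHz/mT); ``GAMMA`` = 2*pi*GAMMA_BAR rad/(ms*µT).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: gyromagnetic ratio over 2 pi, kHz/µT (= kHz per (mT/m * mm))
GAMMA_BAR = 42.577e-3
#: gyromagnetic ratio, rad/(ms*µT)
GAMMA = 2.0 * np.pi * GAMMA_BAR


@dataclass(frozen=True)
class RFWaveform:
    """Complex RF envelope on a uniform time grid.

    Parameters
    ----------
    samples : ndarray
        Complex B1 samples in µT.
    dt : float
        Sample interval in ms.
    """

    samples: np.ndarray
    dt: float

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=complex))
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Total duration n*dt in ms."""
        return self.n * self.dt

    @property
    def peak(self) -> float:
        """Peak |B1| in µT."""
        return float(np.max(np.abs(self.samples))) if self.n else 0.0

    @property
    def time(self) -> np.ndarray:
        """Sample-centre times in ms (0 at the start of the pulse)."""
        return (np.arange(self.n) + 0.5) * self.dt

    @property
    def energy(self) -> float:
        """Integrated |B1|^2 dt, µT²·ms (proportional to deposited RF energy)."""
        return float(np.sum(np.abs(self.samples) ** 2) * self.dt)

    def scaled(self, factor: complex) -> "RFWaveform":
        return RFWaveform(self.samples * factor, self.dt)


@dataclass(frozen=True)
class GradientWaveform:
    """Real gradient samples (mT/m) on the same uniform grid as the RF."""

    samples: np.ndarray
    dt: float

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def time(self) -> np.ndarray:
        return (np.arange(self.n) + 0.5) * self.dt

    @property
    def slew(self) -> np.ndarray:
        """First-difference slew rate, mT/m/ms (length n-1)."""
        return np.diff(self.samples) / self.dt

    @property
    def area(self) -> float:
        """Total gradient area, mT/m * ms."""
        return float(np.sum(self.samples) * self.dt)

    @classmethod
    def constant(cls, amplitude: float, n: int, dt: float) -> "GradientWaveform":
        return cls(np.full(n, float(amplitude)), dt)


@dataclass(frozen=True)
class HardwareLimits:
    """Peak-amplitude limits of the RF and gradient chains.

    b1_max in µT, g_max in mT/m, slew_max in mT/m/ms.
    """

    b1_max: float = 13.0
    g_max: float = 40.0
    slew_max: float = 200.0

    def __post_init__(self):
        if min(self.b1_max, self.g_max, self.slew_max) <= 0:
            raise ValueError("all hardware limits must be strictly positive")

    def with_b1(self, b1_max: float) -> "HardwareLimits":
        return HardwareLimits(b1_max, self.g_max, self.slew_max)


@dataclass(frozen=True)
class PulseDesignSpec:
    """Geometry and method selection for one multiband design.

    ``separation`` is the centre-to-centre slice distance in mm.  For the
    fixed-FOV sweeps ``separation = fov / n_slices``.
    """

    n_slices: int
    tbp: float
    thickness: float  # mm
    separation: float  # mm (centre-to-centre)
    limits: HardwareLimits = field(default_factory=HardwareLimits)
    method: str = "vMB"  # one of MB, MBv, vMB, nlMBv, nlvMB, PINS, MultiPINS

    def __post_init__(self):
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.tbp <= 0 or self.thickness <= 0:
            raise ValueError("tbp and thickness must be positive")
        if self.n_slices > 1 and self.separation <= self.thickness:
            raise ValueError("separation must exceed slice thickness")

    @property
    def positions(self) -> np.ndarray:
        """Slice centres x_n in mm, symmetric about isocentre."""
        n = self.n_slices
        return (np.arange(n) - (n - 1) / 2.0) * self.separation

    @property
    def fov(self) -> float:
        """Slice-pack field of view, mm."""
        return self.n_slices * self.separation


def resample_rf(rf: RFWaveform, n_new: int) -> RFWaveform:
    """Fourier (sinc) resampling of the complex envelope onto ``n_new`` samples.

    The underlying continuous pulse is preserved; used to move an SLR design
    from its filter grid onto a finer playout grid before MB modulation.
    """
    from scipy.signal import resample

    if n_new == rf.n:
        return rf
    new = resample(rf.samples, n_new)
    return RFWaveform(new, rf.duration / n_new)


# ---------------------------------------------------------------------------
# Pulse export: columnar UTF-8 text + JSON sidecar
# ---------------------------------------------------------------------------

def write_pulse(path, rf: RFWaveform, g: GradientWaveform, metadata: dict | None = None):
    """Write time(ms), |B1|(µT), phase(rad), G(mT/m) columns plus a .json sidecar."""
    path = Path(path)
    if rf.n != g.n or abs(rf.dt - g.dt) > 1e-12 * rf.dt:
        raise ValueError("RF and gradient must share one time grid")
    cols = np.column_stack([rf.time, np.abs(rf.samples), np.angle(rf.samples), g.samples])
    header = "time_ms\tabs_b1_uT\tphase_rad\tg_mT_per_m"
    np.savetxt(path, cols, delimiter="\t", header=header, comments="", fmt="%.12e")
    meta = dict(metadata or {})
    meta["dt_ms"] = rf.dt
    meta["n_samples"] = rf.n
    with open(path.with_suffix(path.suffix + ".json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, default=float)


def read_pulse(path):
    """Inverse of :func:`write_pulse`; returns (rf, g, metadata)."""
    path = Path(path)
    data = np.loadtxt(path, skiprows=1)
    with open(path.with_suffix(path.suffix + ".json"), encoding="utf-8") as fh:
        meta = json.load(fh)
    dt = float(meta["dt_ms"])
    rf = RFWaveform(data[:, 1] * np.exp(1j * data[:, 2]), dt)
    g = GradientWaveform(data[:, 3], dt)
    return rf, g, meta
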