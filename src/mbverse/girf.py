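"""Gradient impulse response functions (GIRF): modelling and application.

A gradient chain (amplifier + coil + eddy currents) behaves, to good
approximation, as a linear time-invariant system: the realized gradient is
the demanded waveform convolved with the chain's impulse response,

    G_actual(t) = G_target(t) * h(t),

computed here by frequency-domain multiplication with the measured transfer
function H(f).  Measured GIRFs look like low-pass filters with roughly
linear phase (a constant group delay); :func:`make_synthetic_girf` emulates
that shape with a Gaussian (or Butterworth) magnitude of a chosen FWHM.

Waveforms are zero-padded with edge-hold before the FFT to suppress
circular wrap-around, and the transfer function is linearly interpolated
onto the waveform's frequency grid (flat extrapolation, with a warning,
beyond the measured band).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .waveforms import GradientWaveform

logger = logging.getLogger(__name__)

#: default synthetic magnitude FWHM (kHz), of the order of measured
#: whole-body gradient chains
DEFAULT_FWHM_KHZ = 12.0


@dataclass(frozen=True)
class GIRF:
    """Complex transfer function per gradient axis on a uniform kHz grid."""

    freq_axis: np.ndarray  # kHz
    response: dict  # axis -> complex ndarray

    def __post_init__(self):
        f = np.asarray(self.freq_axis, float)
        object.__setattr__(self, "freq_axis", f)
        if not (f.min() <= 0.0 <= f.max()):
            raise ValueError("GIRF grid must contain 0 frequency")
        for ax, resp in self.response.items():
            if np.asarray(resp).shape != f.shape:
                raise ValueError(f"axis {ax}: response/grid size mismatch")
        dc = abs(self.at(0.0))
        if not 0.95 <= dc <= 1.05:
            logger.warning("GIRF DC magnitude %.3f outside [0.95, 1.05]", dc)

    @property
    def axes(self):
        return tuple(self.response)

    def at(self, f_khz, axis: str = "z"):
        """Linearly interpolated complex response (flat beyond the band)."""
        resp = np.asarray(self.response[axis])
        re = np.interp(f_khz, self.freq_axis, resp.real)
        im = np.interp(f_khz, self.freq_axis, resp.imag)
        return re + 1j * im


def make_synthetic_girf(
    fwhm: float = DEFAULT_FWHM_KHZ,
    delay: float = 0.0,
    shape: str = "gaussian",
    f_max: float | None = None,
    df: float = 0.156,
    axes=("z",),
) -> GIRF:
    """Synthetic low-pass GIRF: |H| with the given FWHM (kHz) and a linear
    phase corresponding to a constant group delay (µs).

    ``shape`` is 'gaussian' or 'butterworth' (4th order).  The grid spans
    ±f_max (default 6x FWHM) at resolution ``df`` kHz.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if f_max is None:
        f_max = 6.0 * fwhm
    # snap the resolution so +-fwhm/2 falls exactly on the grid (keeps the
    # half-maximum definition exact under linear interpolation)
    df = (fwhm / 2.0) / max(round((fwhm / 2.0) / df), 1)
    n = int(np.ceil(f_max / df))
    f = np.arange(-n, n + 1) * df
    if shape == "gaussian":
        mag = np.exp(-4 * np.log(2) * (f / fwhm) ** 2)
    elif shape == "butterworth":
        mag = 1.0 / np.sqrt(1.0 + (2 * f / fwhm) ** 8)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    phase = -2 * np.pi * f * (delay * 1e-3)  # kHz * ms
    resp = mag * np.exp(1j * phase)
    return GIRF(f, {ax: resp for ax in axes})


def identity_girf(f_max: float = 1000.0) -> GIRF:
    f = np.linspace(-f_max, f_max, 3)
    return GIRF(f, {"z": np.ones(3, dtype=complex)})


def apply_girf(g_target: GradientWaveform, girf: GIRF, axis: str = "z") -> GradientWaveform:
    """Predicted realized gradient: frequency-domain application of H(f).

    The waveform is padded to >= 2x length with edge-hold values, the GIRF
    is interpolated onto the waveform's frequency grid (flat extrapolation
    with a warning if the measured band is narrower than Nyquist), and the
    central segment is returned on the input grid.
    """
    gs = g_target.samples
    n = gs.size
    pad = n  # 2x total length, split around the waveform
    ext = np.concatenate([np.full(pad // 2, gs[0]), gs, np.full(pad - pad // 2, gs[-1])])
    m = ext.size
    f = np.fft.fftfreq(m, d=g_target.dt)  # kHz (1/ms)
    if np.max(np.abs(f)) > girf.freq_axis.max() + 1e-9:
        logger.warning(
            "GIRF band (±%.1f kHz) narrower than waveform Nyquist (±%.1f kHz); "
            "holding edge values", girf.freq_axis.max(), np.max(np.abs(f)),
        )
    h = girf.at(f, axis=axis)
    out = np.fft.ifft(np.fft.fft(ext) * h)
    out = out.real[pad // 2 : pad // 2 + n]
    return GradientWaveform(out, g_target.dt)


# ---------------------------------------------------------------------------
# GIRF file I/O: CSV (freq_kHz, re, im) per axis + JSON sidecar
# ---------------------------------------------------------------------------

def write_girf(path, girf: GIRF, provenance: str = ""):
    path = Path(path)
    cols = [girf.freq_axis]
    header = ["freq_kHz"]
    for ax in girf.axes:
        r = np.asarray(girf.response[ax])
        cols += [r.real, r.imag]
        header += [f"re_{ax}", f"im_{ax}"]
    np.savetxt(path, np.column_stack(cols), delimiter=",",
               header=",".join(header), comments="", fmt="%.10e")
    meta = {
        "axes": list(girf.axes),
        "resolution_khz": float(np.median(np.diff(girf.freq_axis))),
        "provenance": provenance,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)


def read_girf(path) -> GIRF:
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    with open(path.with_suffix(path.suffix + ".json"), encoding="utf-8") as fh:
        meta = json.load(fh)
    f = data[:, 0]
    resp = {}
    for i, ax in enumerate(meta["axes"]):
        resp[ax] = data[:, 1 + 2 * i] + 1j * data[:, 2 + 2 * i]
    return GIRF(f, resp)
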