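"""PINS and MultiPINS pulse design.

PINS ("power independent of number of slices") undersamples a singleband
envelope into a train of hard RF subpulses interleaved with gradient blips.
Each blip advances the excitation k-space by exactly one period 2*pi/sep,
so the excitation is periodic in space with period equal to the slice
separation — the pulse excites *every* slice of an infinite comb, and its
duration is independent of how many slices are imaged.

MultiPINS mixes a VERSE-reshaped multiband pulse (RF proportional to the
instantaneous blipped gradient at matched k) into the PINS train with a
mixing ratio M:

    RF_MultiPINS = M * RF_MB,reshaped + (1 - M) * RF_PINS

The MB component delivers flip during the gradient blips, so the RF blips
carry only (1-M) of the subpulse areas and shrink accordingly: raising M
shortens the pulse until the reshaped MB component itself hits B1max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .multiband import ModulationSpec, k_trajectory
from .waveforms import GAMMA_BAR, GradientWaveform, HardwareLimits, RFWaveform


class PinsDesignError(RuntimeError):
    pass


#: default sampling intervals (ms) per time-bandwidth product; short dwells
#: keep the quantized RF blips efficient
DEFAULT_DWELL = {2.0: 1.21e-3, 4.0: 3.37e-3}


@dataclass(frozen=True)
class PinsDesign:
    """A blipped PINS/MultiPINS pulse."""

    rf: RFWaveform
    g: GradientWaveform
    n_subpulses: int
    mixing_ratio: float = 0.0

    @property
    def duration(self) -> float:
        return self.rf.duration


def _gradient_blip(area: float, lim: HardwareLimits, dwell: float) -> np.ndarray:
    """Shortest triangular (or trapezoidal if g_max-limited) lobe of the
    given area (mT/m*ms) on the dwell grid, slew-safe and area-exact."""
    slew = lim.slew_max * 0.995
    t_ramp = np.sqrt(area / slew)
    peak = t_ramp * slew
    if peak <= lim.g_max:
        n_ramp = max(int(np.ceil(t_ramp / dwell)), 1)
        n_flat = 0
    else:
        n_ramp = max(int(np.ceil(lim.g_max / (slew * dwell))), 1)
        t_flat = (area - lim.g_max**2 / slew) / lim.g_max
        n_flat = int(np.ceil(t_flat / dwell))
    while True:
        up = (np.arange(1, n_ramp + 1) - 0.5) / n_ramp
        tri = np.concatenate([up, np.ones(n_flat), up[::-1]])
        blip = tri * (area / (tri.sum() * dwell))
        if blip.max() <= lim.g_max and np.max(np.abs(np.diff(blip))) / dwell <= lim.slew_max:
            return blip
        n_flat += 1  # lengthen until amplitude/slew fit after area scaling


def _rf_blip(area: complex, lim: HardwareLimits, dwell: float) -> np.ndarray:
    """Shortest constant-amplitude hard pulse of the given (complex) area,
    µT*ms; the phase of the area is preserved."""
    if area == 0.0:
        return np.zeros(0, dtype=complex)
    n = max(int(np.ceil(abs(area) / (lim.b1_max * dwell))), 1)
    return np.full(n, area / (n * dwell))


def design_pins(
    sb: RFWaveform,
    tbp: float,
    thickness: float,
    separation: float,
    lim: HardwareLimits,
    dwell: float | None = None,
    area_scale: float = 1.0,
    comb_offset: float = 0.0,
) -> PinsDesign:
    """Pure PINS design by undersampling the singleband envelope.

    ``area_scale`` scales the RF subpulse areas (used internally for the
    (1-M) PINS component of MultiPINS).  The gradient blip area is
    1/(gamma_bar*separation), i.e. a k-step of one spatial period.
    ``comb_offset`` (mm) shifts the excited comb off isocentre via a linear
    inter-subpulse phase ramp — needed when an even number of slices is
    centred symmetrically (slices at half-integer multiples of the
    separation).
    """
    if separation <= thickness:
        raise PinsDesignError("separation must exceed slice thickness")
    if dwell is None:
        dwell = DEFAULT_DWELL.get(float(tbp), 3.37e-3)
    n_sub = int(np.ceil(tbp * separation / thickness))
    # integrate the SB envelope over n_sub equal time bins
    edges = np.linspace(0, sb.n, n_sub + 1).astype(int)
    areas = np.array([
        np.sum(sb.samples[a:b]) * sb.dt for a, b in zip(edges[:-1], edges[1:])
    ]) * area_scale
    if comb_offset:
        areas = areas * np.exp(-1j * 2 * np.pi * np.arange(n_sub)
                               * comb_offset / separation)
    blip_area = 1.0 / (GAMMA_BAR * separation)
    gblip = _gradient_blip(blip_area, lim, dwell)
    if gblip.size == 0:
        raise PinsDesignError("gradient blip unreachable under limits")
    rf_parts, g_parts = [], []
    for j, a in enumerate(areas):
        rb = _rf_blip(a, lim, dwell)
        rf_parts.append(rb)
        g_parts.append(np.zeros(rb.size))
        if j < n_sub - 1:
            rf_parts.append(np.zeros(gblip.size))
            g_parts.append(gblip)
    rf = np.concatenate(rf_parts).astype(complex)
    g = np.concatenate(g_parts)
    return PinsDesign(RFWaveform(rf, dwell), GradientWaveform(g, dwell), n_sub, 0.0)


def _reshape_mb_onto_blips(
    sb: RFWaveform,
    spec: ModulationSpec,
    g_blipped: GradientWaveform,
    g_ref: float = 20.0,
) -> RFWaveform:
    """VERSE-reshape a constant-gradient MB pulse onto the blipped gradient.

    At matched excitation-k the reshaped RF equals the constant-gradient MB
    RF scaled by g(t)/g_ref, so RF is proportional to the instantaneous
    gradient (zero between blips).
    """
    k_const = k_trajectory(GradientWaveform.constant(g_ref, sb.n, sb.dt))
    k_blip = k_trajectory(g_blipped)
    kc = k_const.k - (k_const.k[0] + k_const.k[-1]) / 2.0
    kb = k_blip.k - (k_blip.k[0] + k_blip.k[-1]) / 2.0
    # envelope matched at absolute (centred) k ...
    env_re = np.interp(kb, kc, sb.samples.real)
    env_im = np.interp(kb, kc, sb.samples.imag)
    # ... but the modulation phase must be referenced to a point of the PINS
    # comb (a zero-gradient plateau), not the k-space midpoint: otherwise an
    # even subpulse count anti-phases the odd slices against the comb
    plateaus = kb[g_blipped.samples == 0.0]
    k_ref = plateaus[np.argmin(np.abs(plateaus))] if plateaus.size else 0.0
    f_mod = np.exp(1j * (np.outer(kb - k_ref, spec.positions) + spec.phases)).sum(axis=1)
    return RFWaveform((env_re + 1j * env_im) * f_mod * g_blipped.samples / g_ref,
                      g_blipped.dt)


def design_multipins(
    sb: RFWaveform,
    tbp: float,
    thickness: float,
    spec: ModulationSpec,
    lim: HardwareLimits,
    mixing_ratio: float,
    dwell: float | None = None,
) -> PinsDesign:
    """MultiPINS: PINS with a VERSE-reshaped MB component mixed in.

    The MB modulation uses zero phase offsets (the PINS comb sets the
    inter-slice phase structure).  Raises if the mixed pulse would exceed
    B1max, reporting the measured peak.
    """
    m = float(mixing_ratio)
    if not 0.0 <= m <= 1.0:
        raise ValueError("mixing_ratio must lie in [0, 1]")
    sep = _separation_of(spec)
    offset = comb_offset_of(spec.positions, sep)
    pins = design_pins(sb, tbp, thickness, sep, lim, dwell,
                       area_scale=1.0 - m, comb_offset=offset)
    if m == 0.0:
        return pins
    flat = ModulationSpec(spec.n_slices, spec.positions,
                          np.zeros(spec.n_slices), spec.am_only)
    mb_rf = _reshape_mb_onto_blips(sb, flat, pins.g)
    # align the two components' beta phases at every slice centre (the comb
    # parity otherwise anti-phases alternate slices): measure the small-tip
    # beta of each component on the shared gradient and rotate the MB slice
    # phases to match (scaling the PINS areas does not move its phases)
    k = k_trajectory(pins.g).k
    phase_fix = np.zeros(spec.n_slices)
    for i, x in enumerate(spec.positions):
        e = np.exp(1j * k * x)
        bp = np.sum(pins.rf.samples * e)
        bm = np.sum(mb_rf.samples * e)
        phase_fix[i] = np.angle(bp * np.conj(bm))
    aligned = ModulationSpec(spec.n_slices, spec.positions, phase_fix, spec.am_only)
    mb_rf = _reshape_mb_onto_blips(sb, aligned, pins.g)
    mixed = m * mb_rf.samples + pins.rf.samples  # PINS part already (1-M)-scaled
    peak = float(np.max(np.abs(mixed)))
    if peak > lim.b1_max * (1 + 1e-6):
        raise PinsDesignError(
            f"MultiPINS peak {peak:.3f} µT exceeds B1max {lim.b1_max} µT at M={m}"
        )
    return PinsDesign(RFWaveform(mixed, pins.rf.dt), pins.g, pins.n_subpulses, m)


def comb_offset_of(positions, separation: float) -> float:
    """Offset of the slice comb from isocentre, in (-sep/2, sep/2]."""
    p0 = float(np.min(positions))
    return p0 - separation * np.floor(p0 / separation + 0.5)


def _separation_of(spec: ModulationSpec) -> float:
    if spec.n_slices < 2:
        raise PinsDesignError("PINS-family designs need n_slices >= 2")
    d = np.diff(np.sort(spec.positions))
    if not np.allclose(d, d[0], rtol=1e-6):
        raise PinsDesignError("PINS requires equally spaced slices")
    return float(d[0])


def max_mixing_ratio(
    sb: RFWaveform,
    tbp: float,
    thickness: float,
    spec: ModulationSpec,
    lim: HardwareLimits,
    step: float = 0.005,
    dwell: float | None = None,
) -> float:
    """Largest feasible mixing ratio on the grid {0, step, 2*step, ..., 1}.

    Duration is non-increasing in M over the feasible range, so the largest
    feasible M is also the time-optimal choice.  Raises if even M=0 fails.
    """
    grid = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    design_multipins(sb, tbp, thickness, spec, lim, 0.0, dwell)  # must work
    lo, hi = 0, grid.size - 1
    # feasibility is monotone (the reshaped MB peak scales with M): bisect
    while lo < hi:
        mid = (lo + hi + 1) // 2
        try:
            design_multipins(sb, tbp, thickness, spec, lim, grid[mid], dwell)
            lo = mid
        except PinsDesignError:
            hi = mid - 1
    return float(grid[lo])
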