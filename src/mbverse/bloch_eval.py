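"""Spin-domain Bloch simulation and slice-profile metrics.

Simulation uses the hard-pulse approximation in the Cayley-Klein (SU(2))
representation: each RF sample is a nutation, interleaved with free
precession under the instantaneous gradient (plus any off-resonance).  The
convention matches :mod:`mbverse.slr_design`: for a constant gradient the
simulated (alpha, beta) at position z equal the SLR polynomials evaluated at
z = exp(i * GAMMA * g * x * dt).

Profile metrics follow the flip-angle representation theta(z) =
arccos(Mz(z)) = arccos(1 - 2|beta|^2); refocusing performance uses the
complex beta^2 profile.  NRMSE is split into an inside-FOV term (slice
distortion -> blurring) and an outside-FOV term (ghost slices -> aliasing),
both normalized by the RMS of the target over the inside region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .waveforms import GAMMA, GradientWaveform, RFWaveform


@dataclass(frozen=True)
class SliceProfile:
    """Flip-angle / beta^2 profile on a spatial grid (z in mm)."""

    z: np.ndarray
    flip: np.ndarray  # theta(z), rad
    beta_sq: np.ndarray  # complex beta^2(z)
    fov: float  # inside-region width, mm

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.beta_sq)

    @property
    def inside_mask(self) -> np.ndarray:
        return np.abs(self.z) <= self.fov / 2.0

    @property
    def outside_mask(self) -> np.ndarray:
        return (np.abs(self.z) > self.fov / 2.0) & (np.abs(self.z) <= 1.5 * self.fov)


@dataclass(frozen=True)
class OffResResult:
    """Off-resonance shift and shape distortion of one slice vs frequency."""

    df_axis: np.ndarray  # Hz
    shift: np.ndarray  # mm
    distortion_nrmse: np.ndarray  # fraction


def _compress_events(rf: RFWaveform, g: GradientWaveform, df: float):
    """Merge mergeable sample runs into single rotation events.

    Two exact merges are available:

    * runs of zero-RF samples: free precessions commute, so the run is one
      precession over the summed gradient-time area (any df);
    * on resonance (df == 0) only: runs with constant RF and exactly zero
      gradient are a single nutation of the summed angle (PINS RF blips).

    Returns (b1, g_eff, dt_eff) per-event arrays.
    """
    b1 = rf.samples
    gs = g.samples
    dt = rf.dt
    zero = np.abs(b1) == 0.0
    if not zero.any():
        return b1, gs, np.full(b1.size, dt)
    out_b1, out_g, out_dt = [], [], []
    j = 0
    n = b1.size
    while j < n:
        if zero[j]:
            k = j
            while k < n and zero[k]:
                k += 1
            span = (k - j) * dt
            out_b1.append(0.0)
            out_g.append(float(np.sum(gs[j:k]) * dt / span))
            out_dt.append(span)
            j = k
        else:
            k = j + 1
            if df == 0.0 and gs[j] == 0.0:
                while k < n and gs[k] == 0.0 and b1[k] == b1[j]:
                    k += 1
            out_b1.append(b1[j])
            out_g.append(gs[j])
            out_dt.append((k - j) * dt)
            j = k
    return (np.asarray(out_b1, dtype=complex), np.asarray(out_g, dtype=float),
            np.asarray(out_dt, dtype=float))


@njit(cache=True)
def _ck_sim_events(b1, g, dts, z, df_khz):  # pragma: no cover - numba
    nz = z.size
    nt = b1.size
    alpha = np.ones(nz, dtype=np.complex128)
    beta = np.zeros(nz, dtype=np.complex128)
    gamma = 2.0 * np.pi * 42.577e-3
    for j in range(nt):
        dt = dts[j]
        theta = gamma * np.abs(b1[j]) * dt
        cj = np.cos(theta / 2.0)
        sj = 1j * np.exp(1j * np.angle(b1[j])) * np.sin(theta / 2.0)
        for i in range(nz):
            psi = (gamma * g[j] * z[i] + 2.0 * np.pi * df_khz) * dt
            b = beta[i] * np.exp(-1j * psi)
            a = alpha[i]
            alpha[i] = cj * a - np.conj(sj) * b
            beta[i] = sj * a + cj * b
    return alpha, beta


def spin_domain_sim(
    rf: RFWaveform,
    g: GradientWaveform,
    z_grid: np.ndarray,
    df: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cayley-Klein (alpha, beta) per position in ``z_grid`` (mm).

    ``df`` is the off-resonance frequency in Hz.  Runs of zero-RF samples
    (PINS gradient blips) are merged into single precession events, which is
    exact and makes blipped pulses cheap to simulate.
    """
    if rf.n != g.n or abs(rf.dt - g.dt) > 1e-12 * rf.dt:
        raise ValueError("rf and g must share one uniform time grid")
    z = np.ascontiguousarray(np.asarray(z_grid, dtype=float))
    b1, ge, dts = _compress_events(rf, g, df)
    alpha, beta = _ck_sim_events(
        np.ascontiguousarray(b1), np.ascontiguousarray(ge),
        np.ascontiguousarray(dts), z, df * 1e-3,
    )
    err = np.max(np.abs(np.abs(alpha) ** 2 + np.abs(beta) ** 2 - 1.0))
    if err > 1e-9:
        raise FloatingPointError(f"unitarity violated by {err:.1e}")
    return alpha, beta


def flip_profile(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """theta(z) = arccos(Mz) = arccos(1 - 2|beta|^2), in [0, pi]."""
    b2 = np.abs(beta) ** 2
    if np.max(b2) > 1.0 + 1e-9:
        raise FloatingPointError("|beta|^2 exceeds 1")
    return np.arccos(np.clip(1.0 - 2.0 * b2, -1.0, 1.0))


def refocus_profile(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Complex beta^2 (crushed spin-echo refocusing efficiency)."""
    return beta**2


def simulate_profile(rf, g, z_grid, fov, df: float = 0.0) -> SliceProfile:
    alpha, beta = spin_domain_sim(rf, g, z_grid, df)
    return SliceProfile(np.asarray(z_grid, float), flip_profile(alpha, beta),
                        refocus_profile(alpha, beta), fov)


def default_z_grid(fov: float, thickness: float, points_per_slice: int = 16) -> np.ndarray:
    """Uniform grid over the 3x FOV evaluation window, >= ``points_per_slice``
    samples per slice thickness."""
    dz = thickness / points_per_slice
    half = 1.5 * fov
    n = int(np.ceil(2 * half / dz)) + 1
    return np.linspace(-half, half, n)


def nrmse_regions(profile: SliceProfile, target: SliceProfile) -> tuple[float, float]:
    """(eps_inside, eps_outside) between flip-angle profiles.

    Both are normalized by the RMS of the target over the inside region —
    the target is essentially zero outside, so a shared denominator keeps
    eps_outside comparable across methods.
    """
    if profile.z.shape != target.z.shape or not np.allclose(profile.z, target.z):
        raise ValueError("profiles must share one z grid")
    inside = profile.inside_mask
    outside = profile.outside_mask
    denom = np.sqrt(np.mean(target.flip[inside] ** 2))
    if denom == 0:
        raise ZeroDivisionError("target profile vanishes over the inside region")
    diff = profile.flip - target.flip
    eps_in = np.sqrt(np.mean(diff[inside] ** 2)) / denom
    eps_out = np.sqrt(np.mean(diff[outside] ** 2)) / denom
    return float(eps_in), float(eps_out)


def _in_slice_mask(flip: np.ndarray, z: np.ndarray, positions, separation) -> np.ndarray:
    """Points belonging to a slice: |theta| above half its per-slice max."""
    mask = np.zeros(z.size, dtype=bool)
    for x in np.atleast_1d(positions):
        sl = np.abs(z - x) <= separation / 2.0
        if not sl.any():
            continue
        peak = np.max(flip[sl])
        mask |= sl & (flip >= peak / 2.0)
    return mask


def phase_deviation(
    rf: RFWaveform,
    g_ideal: GradientWaveform,
    g_actual: GradientWaveform,
    z_grid: np.ndarray,
    positions,
    separation: float,
    scale_to: float = np.pi / 4,
) -> float:
    """Mean absolute in-slice phase difference (degrees) caused by gradient
    distortion, after removing the best-fit linear-in-z phase roll.

    The pulse is rescaled so its peak on-resonance flip is ~``scale_to``
    (phase is ill-defined at 180°); the linear roll common to all slices is
    discounted since crushers/rewinders can compensate it.
    """
    z = np.asarray(z_grid, float)
    # two fixed-point iterations put the peak flip at scale_to
    scale = scale_to / np.pi
    for _ in range(2):
        a, b = spin_domain_sim(rf.scaled(scale), g_ideal, z)
        peak = np.max(flip_profile(a, b))
        if peak > 0:
            scale *= scale_to / peak
    rf_s = rf.scaled(scale)
    a_i, b_i = spin_domain_sim(rf_s, g_ideal, z)
    a_d, b_d = spin_domain_sim(rf_s, g_actual, z)
    flip_i = flip_profile(a_i, b_i)
    mask = _in_slice_mask(flip_i, z, positions, separation)
    dphi = np.angle(b_d[mask] * np.conj(b_i[mask]))
    # remove best-fit linear-in-z common roll
    coef = np.polyfit(z[mask], np.unwrap(dphi), 1)
    resid = np.unwrap(dphi) - np.polyval(coef, z[mask])
    return float(np.degrees(np.mean(np.abs(resid))))


def offres_analysis(
    rf: RFWaveform,
    g: GradientWaveform,
    z_grid: np.ndarray,
    slice_center: float,
    slice_halfwidth: float,
    df_grid=None,
) -> OffResResult:
    """Shift and shape distortion of one (outer) slice vs off-resonance.

    Per frequency, the spatial shift is located by maximal cross-correlation
    of |theta| with the on-resonance profile (parabolic sub-sample
    refinement); the distortion is the NRMSE after shift correction.
    """
    if df_grid is None:
        df_grid = np.arange(0.0, 201.0, 25.0)
    df_grid = np.asarray(df_grid, float)
    z = np.asarray(z_grid, float)
    dz = z[1] - z[0]
    win = np.abs(z - slice_center) <= slice_halfwidth
    a0, b0 = spin_domain_sim(rf, g, z)
    ref = flip_profile(a0, b0) * win
    shifts = np.zeros(df_grid.size)
    dist = np.zeros(df_grid.size)
    norm = np.sqrt(np.mean(ref[win] ** 2))
    for i, df in enumerate(df_grid):
        if df == 0.0:
            continue
        a, b = spin_domain_sim(rf, g, z, df=df)
        prof = flip_profile(a, b)
        # cross-correlate over a generous search window
        corr = np.correlate(prof, ref, mode="same")
        j = int(np.argmax(corr))
        if 0 < j < corr.size - 1:
            c0, c1, c2 = corr[j - 1 : j + 2]
            denom = c0 - 2 * c1 + c2
            frac = 0.5 * (c0 - c2) / denom if denom != 0 else 0.0
        else:
            frac = 0.0
        lag = (j + frac) - (corr.size // 2)
        shifts[i] = lag * dz
        shifted = np.interp(z, z - shifts[i], prof)
        dist[i] = np.sqrt(np.mean((shifted[win] - ref[win]) ** 2)) / norm
    return OffResResult(df_grid, shifts, dist)


def profile_to_csv(profile: SliceProfile, path):
    """Export z_mm, theta_rad, re/im beta^2 and region labels."""
    import pandas as pd

    region = np.where(profile.inside_mask, "inside_fov", "outside_fov")
    pd.DataFrame({
        "z_mm": profile.z,
        "theta_rad": profile.flip,
        "re_beta2": profile.beta_sq.real,
        "im_beta2": profile.beta_sq.imag,
        "region": region,
    }).to_csv(path, index=False)
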