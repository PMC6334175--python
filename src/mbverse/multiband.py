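"""Multiband (simultaneous multislice) modulation of singleband pulses.

A singleband pulse is made multiband by multiplying it with a modulation
function that replicates the slice in the frequency domain:

* constant gradient G:   f_N(t)   = sum_n exp(i (GAMMA*G*t*x_n + phi_n))
* time-variable gradient: f_N^v(t) = sum_n exp(i (k(t)*x_n + phi_n)),
  with k(t) = -GAMMA * int_t^T G(s) ds  (rad/mm, k(T) = 0).

Phase offsets phi_n are optimized once per slice count N to minimize the
peak of the modulation (they do not depend on the singleband waveform).
The vMB B1-limit reduction divides the hardware B1 ceiling by max|f_N^v|.

Non-linear-phase multiband designs are produced by root-flipping: selected
passband roots of the multiband beta polynomial are reflected across the
unit circle, trading through-slice phase linearity for lower peak RF; the
flip pattern is chosen by a seeded genetic algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numba import njit
from scipy.optimize import minimize

from .slr_design import (
    SLRFilterSpec,
    minimum_phase_factor,
    TRANSITION_MARGIN,
    _band_edges,
    beta_peak_response,
    beta_to_alpha,
    design_beta_filter,
    leja_order,
    _inverse_recursion,
)
from .waveforms import GAMMA, GradientWaveform, RFWaveform

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModulationSpec:
    """Slice geometry and phase offsets of one multiband modulation."""

    n_slices: int
    positions: np.ndarray  # mm
    phases: np.ndarray  # rad
    am_only: bool = False

    def __post_init__(self):
        object.__setattr__(self, "positions", np.asarray(self.positions, float))
        object.__setattr__(self, "phases", np.asarray(self.phases, float))
        if self.positions.size != self.n_slices or self.phases.size != self.n_slices:
            raise ValueError("positions and phases must have length n_slices")


@dataclass(frozen=True)
class KTrajectory:
    """Excitation k-trajectory (rad/mm) on the RF sample grid.

    Follows the convention k(t) = -GAMMA * int_t^T G ds, so k is exactly 0 at
    the end of the pulse and -GAMMA*(gradient area) at the start.
    """

    k: np.ndarray  # value at each sample position, rad/mm
    dt: float  # ms

    @property
    def n(self) -> int:
        return self.k.size


def k_trajectory(g: GradientWaveform) -> KTrajectory:
    """Cumulative (trapezoid) k(t) of a gradient waveform, k(last sample)=0."""
    gs = g.samples
    # right-sided cumulative trapezoid: k_i = -GAMMA * int_{t_i}^{t_last} G
    rev = np.concatenate([[0.0], np.cumsum((gs[::-1][1:] + gs[::-1][:-1]) / 2.0)])[::-1]
    return KTrajectory(-GAMMA * rev * g.dt, g.dt)


def modulation_constant(spec: ModulationSpec, g_amp: float, n: int, dt: float) -> np.ndarray:
    """f_N(t) samples for a constant gradient; t is measured from the pulse
    center so that symmetric designs stay conjugate-symmetric."""
    t = (np.arange(n) - (n - 1) / 2.0) * dt
    ph = GAMMA * g_amp * np.outer(t, spec.positions) + spec.phases
    return np.exp(1j * ph).sum(axis=1)


def modulate_constant(sb: RFWaveform, spec: ModulationSpec, g_amp: float) -> RFWaveform:
    """Multiband modulation of a singleband pulse on a constant gradient."""
    if g_amp <= 0:
        raise ValueError("g_amp must be positive")
    f = modulation_constant(spec, g_amp, sb.n, sb.dt)
    return RFWaveform(sb.samples * f, sb.dt)


def modulation_verse(spec: ModulationSpec, k: KTrajectory,
                     center_reference: bool = True) -> np.ndarray:
    """f_N^v(t) samples for a time-variable gradient.

    With ``center_reference`` the modulation phase is referenced to the
    k-space midpoint (k_first + k_last)/2 instead of k=0 at the pulse end.
    The two choices differ only by a constant phase per slice, but the
    centered reference keeps symmetric designs conjugate-symmetric and makes
    the constant-gradient case coincide exactly with the Eq-1 style
    time-centered modulation.
    """
    kk = k.k - (k.k[0] + k.k[-1]) / 2.0 if center_reference else k.k
    ph = np.outer(kk, spec.positions) + spec.phases
    return np.exp(1j * ph).sum(axis=1)


def modulate_verse(sb_versed: RFWaveform, k: KTrajectory, spec: ModulationSpec,
                   center_reference: bool = True) -> RFWaveform:
    """Multiband modulation after VERSE, using the k-trajectory of the
    (time-variable) selection gradient."""
    if k.n != sb_versed.n or abs(k.dt - sb_versed.dt) > 1e-12 * sb_versed.dt:
        raise ValueError("k-trajectory and RF must share one time grid")
    f = modulation_verse(spec, k, center_reference)
    return RFWaveform(sb_versed.samples * f, sb_versed.dt)


def vmb_b1_limit(b1_max: float, f_nv: np.ndarray) -> float:
    """Reduced singleband B1 limit for the vMB route: b1_max / max|f_N^v|."""
    peak = float(np.max(np.abs(f_nv)))
    if peak == 0:
        raise ValueError("modulation function vanishes")
    return b1_max / peak


# ---------------------------------------------------------------------------
# Phase-offset optimization
# ---------------------------------------------------------------------------

def _peak_modulation(phases: np.ndarray, u: np.ndarray, tau: np.ndarray) -> float:
    f = np.exp(1j * (2 * np.pi * np.outer(tau, u) + phases)).sum(axis=1)
    return float(np.max(np.abs(f)))


@lru_cache(maxsize=64)
def _cached_phase_offsets(n_slices: int, am_only: bool, seed: int) -> tuple[float, ...]:
    u = np.arange(n_slices) - (n_slices - 1) / 2.0  # normalized slice offsets
    # two full periods of the slowest component, densely sampled
    tau = np.linspace(0.0, 2.0, 4096, endpoint=False)
    if n_slices == 1:
        return (0.0,)
    if am_only:
        # exhaustive over sign patterns (phi in {0, pi}), first slice fixed
        best, best_peak = None, np.inf
        for bits in range(1 << (n_slices - 1)):
            ph = np.zeros(n_slices)
            for j in range(n_slices - 1):
                if bits >> j & 1:
                    ph[j + 1] = np.pi
            p = _peak_modulation(ph, u, tau)
            if p < best_peak:
                best, best_peak = ph, p
        return tuple(best)

    rng = np.random.default_rng(seed)

    def smooth_obj(ph_free, p):
        ph = np.concatenate([[0.0], ph_free])
        f = np.abs(np.exp(1j * (2 * np.pi * np.outer(tau, u) + ph)).sum(axis=1))
        m = f.max()
        return m * (np.mean((f / m) ** p)) ** (1.0 / p)

    starts = [rng.uniform(0, 2 * np.pi, n_slices - 1) for _ in range(31)]
    # deterministic quadratic-phase start (a good heuristic for peak reduction)
    starts.append((np.pi * (np.arange(1, n_slices) + 1) ** 2 / n_slices) % (2 * np.pi))
    best, best_peak = np.zeros(n_slices), _peak_modulation(np.zeros(n_slices), u, tau)
    for x0 in starts:
        x = x0
        for p in (8, 32, 128):
            res = minimize(smooth_obj, x, args=(p,), method="L-BFGS-B",
                           options={"maxiter": 200})
            x = res.x
        ph = np.concatenate([[0.0], x])
        peak = _peak_modulation(ph, u, tau)
        if peak < best_peak:
            best, best_peak = ph, peak
    return tuple(best % (2 * np.pi))


@lru_cache(maxsize=1)
def _bundled_phase_table() -> dict:
    import json
    from importlib import resources

    try:
        with resources.files("mbverse").joinpath("data/phase_offsets.json").open() as fh:
            return json.load(fh)
    except (FileNotFoundError, ModuleNotFoundError):
        return {}


def optimize_phase_offsets(n_slices: int, am_only: bool = False, seed: int = 0) -> np.ndarray:
    """Peak-minimizing phase offsets phi_n for N equally spaced slices.

    The offsets depend only on N (and the AM-only restriction), not on the
    singleband waveform or the slice separation.  For the default seed the
    bundled table (produced by this same optimizer) is used; other seeds
    re-run the multi-start optimization.  With ``am_only`` the phases are
    restricted to {0, pi} and found by exhaustive enumeration.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if seed == 0:
        hit = _bundled_phase_table().get(f"{n_slices}:{int(am_only)}")
        if hit is not None:
            return np.asarray(hit, float)
    return np.asarray(_cached_phase_offsets(n_slices, am_only, seed))


def make_modulation_spec(positions, n_slices=None, am_only=False, seed=0,
                         phases=None) -> ModulationSpec:
    positions = np.asarray(positions, float)
    n = n_slices or positions.size
    if phases is None:
        phases = optimize_phase_offsets(n, am_only=am_only, seed=seed)
    return ModulationSpec(n, positions, np.asarray(phases, float), am_only)


def save_phase_table(path, n_range=range(1, 13), seed: int = 0):
    """Persist optimized offsets as JSON keyed by (N, am_only)."""
    import json

    table = {}
    for n in n_range:
        for am in (False, True):
            table[f"{n}:{int(am)}"] = list(optimize_phase_offsets(n, am, seed))
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(table, fh, indent=1)


# ---------------------------------------------------------------------------
# Root-flipped multiband design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings for the root-flip pattern search."""

    population: int = 48
    generations: int = 60
    mutation: float | None = None  # default 1/n_bits
    elite: int = 2
    seed: int = 1234


def multiband_beta(beta_sb: np.ndarray, spec: ModulationSpec, tbp: float,
                   thickness: float) -> np.ndarray:
    """Multiband beta polynomial: the SB beta modulated at the band centers.

    The per-sample band-center angles are w_n = 2*pi*tbp*x_n/(n*thickness);
    an error is raised if any band approaches the polynomial Nyquist limit.
    """
    n = beta_sb.size
    w = 2 * np.pi * tbp * spec.positions / (n * thickness)
    half_bw = np.pi * tbp * (1 + TRANSITION_MARGIN) / n
    if np.max(np.abs(w)) + half_bw > 0.9 * np.pi:
        raise ValueError(
            "slice positions alias on this beta grid; increase n_samples"
        )
    idx = np.arange(n) - (n - 1) / 2.0
    mod = np.exp(1j * (np.outer(idx, w) + spec.phases)).sum(axis=1)
    b = beta_sb * mod
    return b / beta_peak_response(b) * beta_peak_response(beta_sb)


def _passband_roots(roots: np.ndarray, band_angles: np.ndarray,
                    half_bw: float) -> np.ndarray:
    """Indices of the passband roots — the flip candidates.

    Roots are flipped individually (the resulting pulses are complex in
    general), matching the root-flipping design family this follows.
    """
    ang = np.angle(roots)
    in_band = np.zeros(roots.size, dtype=bool)
    for w in band_angles:
        d = np.angle(np.exp(1j * (ang - w)))
        in_band |= np.abs(d) <= half_bw
    in_band &= (np.abs(roots) > 0.2) & (np.abs(roots) < 5.0)
    return np.nonzero(in_band)[0]


@njit(cache=True)
def _leja_poly(r):  # pragma: no cover - numba
    """Monic polynomial coefficients (descending powers) from roots,
    accumulated in Leja order for numerical stability."""
    n = r.size
    ordered = np.empty(n, dtype=np.complex128)
    left = r.copy()
    dist = np.abs(left)
    m = n
    for j in range(n):
        idx = 0
        best = -1.0
        for i in range(m):
            if dist[i] > best:
                best = dist[i]
                idx = i
        ordered[j] = left[idx]
        m -= 1
        left[idx] = left[m]
        dist[idx] = dist[m]
        for i in range(m):
            dist[i] *= np.abs(left[i] - ordered[j])
    c = np.zeros(n + 1, dtype=np.complex128)
    c[0] = 1.0
    for j in range(n):
        root = ordered[j]
        for k in range(j + 1, 0, -1):
            c[k] = c[k] - root * c[k - 1]
    return c


#: FFT grid for genetic-algorithm fitness evaluations; coarser than the
#: final-construction grid but ample for a peak-|RF| comparison
_GA_FFT = 1 << 14


def _peak_rf_of_beta(b: np.ndarray, dt: float) -> float:
    """Fast peak |RF| (µT) of the 180° pulse for beta ``b`` (GA fitness)."""
    bf = np.fft.fft(b, _GA_FFT)
    b = b / np.max(np.abs(bf))
    mag2 = np.maximum(1.0 - np.abs(np.fft.fft(b, _GA_FFT)) ** 2, 0.0)
    a = minimum_phase_factor(mag2, b.size)
    rot = _inverse_recursion(np.ascontiguousarray(a), np.ascontiguousarray(b.astype(complex)))
    return float(np.max(np.abs(rot))) / (GAMMA * dt)


def _rf_from_beta(b: np.ndarray, dt: float, precise: bool = False) -> RFWaveform:
    """180° RF from a beta polynomial scaled to unit peak response."""
    b = b / beta_peak_response(b)
    a = beta_to_alpha(b, precise=precise)
    rot = _inverse_recursion(np.ascontiguousarray(a), np.ascontiguousarray(b))
    return RFWaveform(rot / (GAMMA * dt), dt)


def root_flip_mb(
    beta_spec: SLRFilterSpec,
    spec: ModulationSpec,
    thickness: float,
    duration: float,
    ga: GAConfig = GAConfig(),
) -> RFWaveform:
    """Root-flipped non-linear-phase multiband refocusing pulse.

    Designs the multiband beta polynomial (phase offsets from ``spec`` are
    ignored: the flip pattern supplies the inter-slice phases), then searches
    flip patterns of the passband roots with a seeded genetic algorithm to
    minimize peak RF at the given ``duration`` (ms).  When the pattern space
    is small enough it is enumerated exhaustively instead.
    """
    b_sb = design_beta_filter(SLRFilterSpec(
        beta_spec.n_samples, beta_spec.tbp, beta_spec.ripple_pass,
        beta_spec.ripple_stop, "linear", beta_spec.pulse_type))
    flat = ModulationSpec(spec.n_slices, spec.positions,
                          np.zeros(spec.n_slices), spec.am_only)
    b_mb = multiband_beta(b_sb, flat, beta_spec.tbp, thickness)
    n = b_mb.size
    dt = duration / n
    tiny = 1e-10 * np.max(np.abs(b_mb))
    nz = np.nonzero(np.abs(b_mb) > tiny)[0]
    lead, last = nz[0], nz[-1]
    roots = np.roots(b_mb[lead : last + 1])
    w_bands = 2 * np.pi * beta_spec.tbp * spec.positions / (n * thickness)
    fp, fs = _band_edges(n, beta_spec.tbp, *beta_spec.beta_ripples)
    cand = _passband_roots(roots, w_bands, 2 * np.pi * fs)
    n_bits = cand.size
    if n_bits == 0:
        return _rf_from_beta(b_mb, dt, precise=True)

    def build(bits: np.ndarray) -> np.ndarray:
        r = roots.copy()
        idx = cand[bits]
        r[idx] = 1.0 / np.conj(r[idx])
        core = _leja_poly(np.ascontiguousarray(r))
        out = np.zeros(n, dtype=complex)
        out[lead : lead + core.size] = core
        return out

    def fitness(bits: np.ndarray) -> float:
        return _peak_rf_of_beta(build(bits), dt)

    rng = np.random.default_rng(ga.seed)
    budget = ga.population * (ga.generations + 1)
    if (1 << n_bits) <= budget:
        # exhaustive enumeration
        patterns = ((np.arange(1 << n_bits)[:, None] >> np.arange(n_bits)) & 1).astype(bool)
        scores = np.array([fitness(p) for p in patterns])
        best = patterns[int(np.argmin(scores))]
        best_score = float(scores.min())
    else:
        pmut = ga.mutation if ga.mutation is not None else 1.0 / n_bits
        pop = rng.integers(0, 2, size=(ga.population, n_bits)).astype(bool)
        pop[0] = False  # linear-phase pattern
        pop[1] = True  # fully flipped
        # within-band alternating seed: sorting by angle interleaves the
        # reciprocal root pairs, a strong starting pattern in practice
        ang = np.angle(roots[cand])
        band_of = np.argmin(np.abs(np.angle(np.exp(
            1j * (ang[:, None] - w_bands[None, :])))), axis=1)
        rel = np.angle(np.exp(1j * (ang - w_bands[band_of])))
        seed = np.zeros(n_bits, dtype=bool)
        for bi in range(spec.n_slices):
            sel = np.nonzero(band_of == bi)[0]
            seed[sel[np.argsort(rel[sel])][::2]] = True
        pop[2] = seed
        scores = np.array([fitness(ind) for ind in pop])
        for _ in range(ga.generations):
            order = np.argsort(scores)
            pop, scores = pop[order], scores[order]
            new = [pop[i].copy() for i in range(ga.elite)]
            while len(new) < ga.population:
                i1 = int(min(rng.integers(ga.population, size=2)))
                i2 = int(min(rng.integers(ga.population, size=2)))
                mask = rng.random(n_bits) < 0.5
                child = np.where(mask, pop[i1], pop[i2])
                child ^= rng.random(n_bits) < pmut
                new.append(child)
            pop = np.array(new)
            scores[ga.elite:] = [fitness(ind) for ind in pop[ga.elite:]]
        best = pop[int(np.argmin(scores))]
        best_score = float(scores.min())
    logger.info("root_flip_mb: N=%d bits=%d best peak %.2f µT", spec.n_slices,
                n_bits, best_score)
    return _rf_from_beta(build(best), dt, precise=True)
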