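# Methods

`mbverse` designs multiband (MB) refocusing pulses for simultaneous
multislice MRI and evaluates how a real gradient chain distorts their slice
profiles.  This note records the models, the numerical choices and the
limits of what the test suite demonstrates.

## Spin-domain model

All simulation and design work in the Cayley–Klein (SU(2)) representation
under the hard-pulse approximation: an RF sample of complex amplitude
`b1` over a dwell `dt` is a nutation of angle `γ|b1|dt` about a transverse
axis set by the RF phase; free precession between samples contributes a
z-rotation `γ g z dt + 2π Δf dt`.  For a constant gradient the accumulated
(α, β) parameters are polynomials in `z⁻¹ = e^{-iψ}` — the Shinnar–Le Roux
(SLR) picture — and pulse design becomes FIR filter design on β.  The
proton gyromagnetic ratio is γ/2π = 42.577 kHz/mT throughout; units are
µT, mT/m, mm, ms (so mT/m·mm ≡ µT, which keeps gradient and RF terms on
one scale).

Conventions worth knowing:

* precession is applied to β as `β ← β·e^{-iψ}` before each nutation, so
  the simulator agrees with the SLR polynomials to machine precision for a
  constant gradient (a unit test asserts this indirectly via a
  rotation-matrix oracle);
* runs of zero-RF samples are merged into single precession events
  (exact), and on resonance runs of constant RF at zero gradient merge
  into single nutations — this is what makes the multi-million-sample PINS
  trains cheap to simulate;
* flip angle is θ = arccos(1 − 2|β|²); refocusing efficiency is the
  complex β².

## Singleband design

`design_beta_filter` maps the profile ripples (in- and out-of-slice, both
1 % by default) to β-filter ripples: δ₁/4 in-slice (crushed spin-echo
relation) and δ₂ directly out-of-slice.  The out-of-slice choice follows
the convex/root-flip FIR design family these pulses derive from; the
alternative √δ₂ table mapping would allow 10 % β sidelobes that dominate
the out-of-band flip-angle profile and obscure the ghost-slice mechanism
this package exists to study (see the README's reproduction section).

The equiripple design (scipy's Remez exchange, with a weighted
least-squares fallback on an exact even/odd-symmetric basis) is attempted
on a ladder of transition widths — 1.0×, 1.15×, 1.3×, 1.5× the Kaiser
estimate — and the sharpest design whose *measured* ripples meet the
mapped targets wins.  TBP = 2 cannot meet these targets at any length
(the required transition exceeds the half-bandwidth); the best design
within a bounded common relaxation (measured ≈ 2.4×) is accepted with a
warning.  Filters are designed at 512 taps and the resulting pulse is
sinc-resampled onto a 2048-sample playout grid, which keeps the widest
multiband band of the studied geometries ≥ 4× below Nyquist.

Minimum-phase designs reflect every root of the linear-phase β into the
unit disc (same magnitude response exactly); quadratic-phase designs then
reflect the lower-half-plane roots back out.  Root manipulation uses Leja
ordering; the minimum-power α is obtained by cepstral spectral
factorization of 1 − |B|².  At flip = 180° that function has tangential
zeros and the cepstral method converges slowly, so final pulse
construction uses a 2²² grid (≈2·10⁻⁵ residual β error, ≈0.8° at slice
centre); the genetic-algorithm fitness path uses a 2¹⁴ grid, ample for
peak comparisons.  A consequence worth noting: with the mapped TBP-4
ripples the transition occupies ~70 % of the half-band, the design has
little passband-root structure, and quadratic phase barely lowers the
peak (the classic energy-spreading gain appears clearly at TBP 8).

## Multiband modulation and phase offsets

Constant-gradient modulation multiplies the singleband pulse by
`f_N(t) = Σ exp(i(γG t x_n + φ_n))` with t = 0 at the pulse centre; after
VERSE the argument becomes the excitation k-trajectory
`k(t) = −γ∫_t^T G ds`.  `modulate_verse` references the modulation phase
to the k-space midpoint, which differs from the k(T) = 0 convention only
by a constant phase per slice but makes the constant-gradient case agree
with the time-centred form sample-for-sample and keeps symmetric designs
conjugate-symmetric.

Phase offsets φ_n minimize the peak of f_N and depend only on N; they are
found by multi-start smooth-minimax optimization (32 starts, escalating
p-norms) and shipped as a JSON table for N = 1..12 (regenerated by the
same optimizer for other seeds).  With `am_only` the offsets are
restricted to {0, π} and enumerated exhaustively.

At 180° the modulation picture is only approximate: neighbouring bands
impose a cross-band (Bloch–Siegert-like) shift ~(γB1)²/(2Δf) on each
slice, ≈0.03 mm at 28 mm separation for these pulses.  The
shifted-singleband fidelity property is therefore asserted at the
fixed-FOV N = 3 geometry (67 mm separation, measured ≈1.5 % NRMSE); at
28 mm it rises to ≈3.7 %.

## Time-optimal VERSE

The minimum-duration reshaping reparameterizes by traversed gradient area
p (∝ |k|): the speed v(p) = g is capped by g_max and by
`b1_max·|g/rf|` at matched k, accelerations by the slew rate via
`dv²/2dp ≤ s_max`.  A forward (accelerating) and backward (decelerating)
pass over the caps gives the time-optimal speed profile; time and
waveforms are then resampled onto a uniform output dwell.  The arc grid
oversamples the input 8×; the RF cap carries a 2.5·10⁻⁴ back-off so that
interpolation between the arc and time grids cannot breach the limits
(residual sub-10⁻³ overshoots of |RF| are clipped — far below the 1 %
profile-preservation contract).  The output dwell for profile work keeps
the fastest band's per-sample phase increment below π/24
(`recommended_dwell`); durations are insensitive to it.

The vMB route applies VERSE to the singleband pulse under the reduced
limit `b1_max / max|f_N^v|` (the modulation peak), then modulates with the
VERSEd k-trajectory.  Because the traversed k-range does not depend on
traversal speed, the damped fixed-point iteration over this coupling
converges at once.  Durations exclude the gradient ramps to/from zero
outside the RF window; `with_ramps` appends slew-limited ramps when a
waveform is pushed through the gradient-chain model, where the
surroundings matter.

## PINS and MultiPINS

PINS undersamples the singleband envelope into `ceil(TBP·sep/th)` complex
subpulse areas; RF blips run at B1max (duration per blip as dictated by the
area), gradient blips are the shortest triangular/trapezoidal lobes of
area 1/(γ̄·sep) under the slew and amplitude limits, on a 1.21 µs (TBP 2) or
3.37 µs (TBP 4) dwell.  An even, symmetric slice pack sits at half-integer
multiples of the separation; a linear inter-subpulse phase ramp shifts the
excitation comb accordingly.  MultiPINS adds a VERSE-reshaped MB component
(RF ∝ instantaneous gradient at matched k, envelope and modulation taken at
absolute centred k so its slices land exactly on the comb), mixed as
`M·RF_MB + (1−M)·RF_PINS`; the two components' β phases are aligned
per-slice from their small-tip responses before mixing.  The mixing ratio
is the largest feasible value on a 0.005 grid (feasibility is monotone in
M, so a bisection finds the same value the prescribed scan would).

The nominal target of a MultiPINS pulse is full flip on the imaged comb
positions and the profile of the (1−M)-scaled singleband pulse on the
rest (an under-driven 180° develops characteristic shoulders; a linearly
scaled flip angle is the wrong reference).  Even against this target the
linear RF mixing at 180° carries an inherent ≈2–3 % in-pack residual at
the time-optimal M (0.45–0.9 for the studied geometries) — the
superposition in Eq-style mixing is exact only in the small-tip limit.
This is the one family for which the blanket 2 % in-pack design-fidelity
criterion is not met; the number is reported honestly rather than the
target redefined.

## Gradient-chain model

`apply_girf` multiplies the waveform spectrum by the measured/synthetic
transfer function, after edge-held padding to twice the length
(suppressing circular wrap) and linear interpolation of the response onto
the waveform's frequency grid, with flat extrapolation and a warning
beyond the measured band.  The synthetic generator produces a Gaussian (or
8th-order Butterworth) magnitude of chosen FWHM with linear phase (a
constant group delay), emulating the low-pass character of measured
gradient chains.  The default FWHM is 12 kHz with sub-µs delay: in the
range of published whole-body chains, far above the ≤4 kHz content of the
singleband VERSE gradients and far below the ≥20 kHz multiband modulation
sidebands — the regime in which the MBv/vMB distortion asymmetry lives.
The Gaussian attenuates in-band frequencies more than a measured (flat-top)
response does, so absolute inside-pack errors are, if anything,
pessimistic.

## Problem sizes

Evaluation grids cover 3× the slice-pack FOV at ≥16 points per slice
thickness (halving the spacing moves the error metrics by <2 % relative).
The root-flip genetic algorithm uses a 48-member population for 60
generations with bit-flip mutation 1/n_bits, elitism of two, seeded
tournament selection, a within-band alternating seed pattern, and an
exhaustive-enumeration fallback when the whole pattern space fits in that
budget; the sweep statistics in `scripts/acceptance.py` cover N = 2..12 at
TBP 4.  On one CPU the full acceptance computation takes a few minutes,
dominated by the root-flip searches.

## Known limitations

* No relaxation during the pulse and no B1+ inhomogeneity.
* The gradient chain is assumed linear and time-invariant; only the slice
  axis is distorted (multi-axis support is structural).
* Root-flip peak reduction is bounded by the flip-pattern space of the
  modulated equiripple β polynomial: for N = 3 the space was enumerated
  exhaustively and the best constant-gradient peak ratio over the
  phase-optimized linear design is ≈2.1×, with a matching L1-norm argument
  showing the flattened pulses cannot also undercut the linear MBv
  durations after VERSE.  Published gaps based on other root-flip recipes
  can be larger; see the README's reproduction notes.
* Synthetic gradient chains are smooth low-pass models; measured responses
  have in-band structure (mechanical resonances) that the generator does
  not emulate, so passing tests demonstrate the modulation-sideband
  mechanism, not agreement with any particular scanner.
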