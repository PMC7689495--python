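# Methods

## Model and assumptions

The simulator treats the cochlea as a fluid-filled duct of varying
effective cross-section `S(x)` and radius `h(x)`, partitioned by a
compliant cochlear partition (CP) of width `b(x)` and volumetric
stiffness `k(x)`. The fluid is incompressible and inviscid; the model is
linear (no level dependence); the helicotrema is ignored (the WKB
solution is a pure forward wave, and the finite-difference oracle uses an
outgoing apical radiation condition by default). All internal quantities
are SI; millimetres and kilohertz appear only at the I/O boundary.

Mass conservation and Newton's law give a Webster horn equation for the
cross-section-averaged transpartition pressure, with complex wavenumber
`κ = sqrt(−α Z̄ Y_CP)` where `Z̄ = iωρb/S` is the series fluid-mass
impedance and `α = κh/tanh(κh)` the short-wave pressure gain — the ratio
of the pressure at the partition to the cross-section average. In the
long-wave limit (`|κh| ≪ 1`) `α → 1`; near the response peak `|κh| ≫ 1`
and `α ≈ κh` boosts the drive to the partition. The WKB amplitude follows
from energy conservation, `P₀ ∝ α·sqrt(S(0)κ(0)/(Sκ))·e^{−i∫κ}`.

## Tonotopic map and tapers

Greenwood map `CF(x) = A(10^{2.1(1−x/L)} − γ)` with cat-like defaults
A = 456 Hz, γ = 0.8, L = 25 mm; the basal space constant is
`ℓ = L/(2.1 ln 10) ≈ 5.17 mm` and the local warping factor
`η(x) = (ℓ/x)·ln(CF(0)/CF(x))` grows toward the apex for γ > 0.

Tapers (defaults, all configurable, or replaceable by a user-supplied
columnar profile table):

| quantity | form | default scale | rationale |
|---|---|---|---|
| CP stiffness `k` | `k₀ e^{−x/ℓ}` | k₀ = 4×10⁹ Pa/m | one stiffness decade per map decade; k₀ set so the basal wave-front delay `ℓ√(m̄/k)·CF ≈ 1.5` CF periods, the constant value seen in basal mechanics |
| scalae area `S` | `e^{−x/ℓ}` → `e^{−x/2ℓ}` logistic blend of log-slopes | S₀ = 1 mm², blend center 0.6 L, width 0.1 L | anatomical regime change between base and apex; the "chinchilla" regime uses `e^{−x/2ℓ}` throughout |
| scalae radius `h` | `L(0.0475 e^{−x/2ℓ} + 0.015)` | — | fit that captures the cross-species radius taper |
| BM width `b` | linear `b₀ → b₁` | 0.1 → 0.3 mm | small compared to the area variation |
| fluid density | constant | 1000 kg/m³ | water-like perilymph |

The acoustic mass is `m̄ = ρb/S`, so with constant `b` the base has
`m̄ ∝ e^{x/ℓ}` and `m̄k` spatially constant — the tapering-symmetry
condition that keeps both the tail-frequency wave amplitude and the
characteristic impedance `Z₀ ≈ sqrt(m̄k)` constant. The box control holds
`S`, `h`, `b` at their basal values and rescales `k` so that the
long-wave wavenumber profile matches the tapered model pointwise; only
the geometric (horn) factor then differs between the two models.

## Partition admittance

`Y_CP = i·2πf/(k(x)·D(β))` with `D` a function of `β = f/CF(x)` only
(strict scaling symmetry: micromechanical tuning is identical at every
place). The implemented filter is

    D(b) = 1 − b² + i·b·[δ + δ_act·exp(−(b−b_act)²/(2w_act²))],
    b = β/β_r,

a broad oscillator (δ = 0.4) with a Gaussian active undamping window
(δ_act = −0.55, centered at b_act = 0.75, width w_act = 0.15) and the
resonance placed at `β_r = 1.07` times the nominal CF so that the
simulated gain functions peak at CF (f_peak/CF ≈ 0.94–0.98 across sites).
An optional delayed stiffness-feedback term `ρ_f e^{−2πi b T_f}` is
retained for experimentation (default off). Configurations whose `|D|`
approaches zero anywhere on real β (min |D| < 10⁻³) are rejected as
near-singular; the defaults have min |D| ≈ 0.18, so the local filter is
low-Q everywhere and the tall, sharp basal responses arise from wave
mechanics (active accumulation plus short-wave focusing), not from the
filter.

Why this form rather than a pure delayed-feedback ("Zweig-type")
oscillator: at the physical wave-front-delay scale (κℓ ≈ 9 at β = 1) the
short-wave gain `α ≈ κh` amplifies any deep minimum of `|D|`
quadratically in κ. Delayed-feedback parameterizations whose tall-broad
character relies on a near-singular dip (min |D| ~ 0.01) then produce
traveling-wave gains of hundreds of dB and uniformly sharp tuning —
unphysical. Wide parameter scans of the delayed-feedback family found no
stable member that yields the observed base-to-apex decline of gain and
Q_ERB; the windowed-undamping form achieves it with peak gains of
~37 dB (base) to ~11 dB (apex) and Q_ERB ≈ 13 → 5. The window
parameters were chosen once to place basal Q_ERB near the cat ANF range
(~10–13) with a tall enough peak that coherent reflection is dominated
by the peak region (see below).

## Numerics

- Uniform grid, default 4096 points (≥ 20 points per wavelength at the
  shortest simulated wavelength; a warning is issued otherwise).
- α–κ fixed point: seeded at α = 1 (long-wave), pointwise iteration with
  automatic under-relaxation (mixing 0.5) when the residual stalls;
  default tolerance 10⁻⁶ relative, 100 iterations. The iteration runs on
  the principal branch (Re κ ≥ 0) where tanh is well behaved. Points that
  stall — typically the evanescent strip just apical of the peak, where
  the fundamental root lies near the imaginary axis and tanh oscillates —
  are repaired by damped Newton on the equivalent scalar dispersion
  relation `u·tanh u = −Z̄Yh²`, continued in x from the nearest converged
  basal neighbor so that the fundamental transverse mode is followed.
- Branch selection: forward waves have Re κ ≥ 0; where the wave is
  evanescent-dominated (|Im κ| > |Re κ|) the apically bounded, decaying
  branch (Im κ < 0) is selected — the standard WKB connection across a
  turning point. Because α is even in κh the selected root satisfies the
  same dispersion relation.
- Phase integral: trapezoidal on the grid. Finite-difference oracle:
  second-order conservative stencil, banded solve, ghost-node radiation
  conditions (`outgoing`, `pressure-release` apical; `dirichlet`,
  `incident` basal).
- Click synthesis: transfer function sampled on a uniform grid over
  [CF/16, 4 CF], raised-cosine band edges (10% of the band each side),
  embedded in a 2¹⁴-point spectrum; waveform, envelope, and instantaneous
  frequency from the analytic signal. Glide slope: least-squares slope of
  f_inst(t) over the contiguous window where the envelope exceeds 50% of
  its maximum, normalized by CF². The 50% gate is this package's
  operationalization of "near the envelope peak"; gates of 30–90% do not
  change the sign of the measured slopes.
- Q_ERB: `f_peak / (∫|T|²df / max|T|²)` by trapezoid on the sampled grid.
- SFOAE: roughness is multiplicative on Y_CP (hence on κ²), spatially
  white on the grid, zero-mean Gaussian with RMS amplitude 0.01, seeded
  per ear. The first-order reflectance is
  `R = −(i/2)∫ε κ e^{−2i∫κ}dx` (sign fixed by the outgoing 1-D Green's
  function under the `e^{+iωt}` convention and verified to ~1–7% against
  the perturbed finite-difference solution; the Born-vs-FD residual is
  the WKB amplitude error, not a function of ε). Phase-gradient delay
  `N = −(f/2π)dφ/df` with centered differences; the log-frequency grid
  must satisfy Δln f < 1/(2N_max) for clean unwrapping — the default
  ensemble grid uses 512 points over 0.2–10 kHz. Trend lines: Q_ERB
  interpolated log-log from site metrics; N median across ears followed
  by a 31-point rolling median; the tuning ratio is the ratio of these
  trends. Middle-ear transmission is frequency-flat; N is computed from
  the intracochlear basal reflectance directly.

## What the simulations do and do not show

The model generates all its own inputs (no external data). Passing tests
demonstrate the internal consistency of the wave solution (WKB vs direct
finite differences), the analytic tapering-symmetry results (8ℓ apical
attenuation constant; 2ℓ box decay; constant basal wave-front delay;
apical delay exponent ≥ 1/4), and the qualitative tonotopic trends
(monotone base-to-apex decline of Q_ERB and peak gain; upward basal
glides; SFOAE delays ≈ twice the forward group delay near CF; tuning
ratio flat in the base and rising severalfold toward the apex). They do
not demonstrate quantitative agreement with any particular animal's
measured responses: the admittance filter is a minimal stand-in
calibrated only through the defaults above, middle-ear and neural
transduction stages are absent, and fluid viscosity and the helicotrema
are ignored.

## Known limitations

- **Glide-reversal frequency.** The model produces upward glides at
  basal and middle sites and downward glides in the extreme apex, with
  the sign change at ≈ 0.15 kHz — roughly 1.6× the apical CF floor
  `A(1−γ) = 91 Hz` — rather than near 1 kHz as observed in cat. The
  reversal mechanism (map-bend warping making response onsets
  above-CF-dominated) is present but weaker than in the measurements:
  with a strictly scaling-symmetric single-resonance admittance, apical
  responses remain too sharply tuned (Q_ERB ≈ 5 at 0.3 kHz vs ≈ 2 in cat
  ANF data) and their above-CF shoulder too weak for the early
  high-frequency energy to dominate the onset at sites above ~0.2 kHz.
  The corresponding acceptance test is left failing on purpose.
- Apical Q_ERB declines monotonically but not as far as the neural data.
- The WKB amplitude is unreliable within a few grid points of a true
  turning point; observables are insensitive because the response there
  is orders of magnitude below the peak.
- The Born reflectance inherits WKB accuracy; at tail frequencies in the
  base (wavelength ≫ taper scale) it can deviate several percent from
  the exact scattered field.
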