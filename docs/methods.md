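# Methods

## The model

The Györgyi–Field (GF) reduction describes the Belousov–Zhabotinsky
reaction in a continuous-flow stirred-tank reactor by three dimensionless
concentrations `x = X/X₀` (HBrO₂), `z = Z/Z₀` (Ce⁴⁺) and `v = V/V₀`
(bromomalonic acid), evolving in dimensionless time `τ = t/T₀`:

```
dx/dτ = T₀ ( −k₁H Y₀ x ỹ + (k₂AH²Y₀/X₀) ỹ − 2k₃X₀ x²
             + 0.5 k₄ A^0.5 H^1.5 X₀^−0.5 (C − Z₀ z) x^0.5
             − 0.5 k₅Z₀ x z − kf x )
dz/dτ = T₀ ( k₄ A^0.5 H^1.5 X₀^0.5 (C/Z₀ − z) x^0.5 − k₅X₀ x z
             − α k₆ V₀ z v − β k₇ M z − kf z )
dv/dτ = T₀ ( (2k₁H X₀Y₀/V₀) x ỹ + (k₂AH²Y₀/V₀) ỹ + (k₃X₀²/V₀) x²
             − α k₆ Z₀ z v − kf v )
```

with the quasi-steady-state bromide

```
ỹ = ( α k₆ Z₀ V₀ z v / (k₁H X₀ x + k₂AH² + kf) ) / Y₀ .
```

Rate constants (M⁻ⁿ s⁻¹): k₁ = 4.0×10⁶, k₂ = 2.0, k₃ = 3000, k₄ = 55.2,
k₅ = 7000, k₆ = 0.09, k₇ = 0.23. Concentrations (M): A = 0.1 (bromate),
H = 0.26 (acid), M = 0.25 (malonic acid), C = 8.33×10⁻⁴ (total cerium);
stoichiometric factors α = 666.7, β = 0.3478. The flow rate `kf` (s⁻¹) is
the single free parameter; the study interval is (3×10⁻⁴, 5×10⁻⁴).

In the z-equation the concentration factor `X^0.5` is read as
`X₀^0.5 · x^0.5` (the same split every other term uses); the parallel
x-equation term makes this the only dimensionally consistent reading.

### Scaling constants

The dimensionless formulation needs five scales. The concentration scales
are the standard combinations of this reduction:

| scale | expression | value |
|---|---|---|
| X₀ | k₂AH²/k₅ | 1.9314×10⁻⁶ M |
| Z₀ | CA/(40M) | 8.33×10⁻⁶ M |
| V₀ | 4AHC/M² | 1.3861×10⁻³ M |
| Y₀ | 4k₂AH²C/(k₅M²) | 1.0297×10⁻⁷ M |
| T₀ | 1/(k₄A^0.5H^1.5X₀^0.5) | 310.93 s |

Two structural facts matter here. First, `Y₀` cancels identically from
the vector field — each `Y₀·ỹ` product collapses to the dimensional
quasi-steady-state bromide — so its value only sets the reporting scale of
`ỹ`. Second, `T₀` multiplies the whole field, so it is a pure unit of
time: it cannot move bifurcation points in `kf`, only rescale rates and
Lyapunov exponents. The concentration scales are therefore validated by
the regime structure itself (the model reproduces a period-1 cycle at
kf = 3×10⁻⁴, a period-2 cycle at 3.2×10⁻⁴ and a chaotic attractor at
3.5×10⁻⁴, plus the regular/chaotic interval layout across the whole
sweep), while `T₀` is fixed as the time unit that normalizes the cerium
autocatalysis coefficient of the z-equation to one — the choice under
which the maximal exponent of the chaotic showcase lands at its reference
magnitude (≈ 3.4 per unit τ). Exponents in other conventions rescale
linearly with `T₀`.

## Simulation protocol

From `(x₀, z₀, v₀) = (1, 1, 1)` the flow is integrated to `τ = 100` and
sampled on a uniform `10⁻⁴` grid (1,000,001 samples); the first 80% of
each run is discarded so all statistics describe the attractor
(200,001 kept samples starting at τ = 80). The scalar observable for the
map-like indicators is `s(t) = √(x² + z² + v²)`, resampled at stride 100
(≈ 2,001 samples, roughly 11 per oscillation period): the 0–1 test
assumes map-like sampling and heavily oversampled flows bias K toward 0.
The stride is a config knob and covered by a sensitivity test.

The default integrator is an adaptive Dormand–Prince 5(4) pair (the
ode45/RK45 tableau) with the Shampine quartic dense-output interpolant,
numba-compiled because a desk-scale sweep performs hundreds of `τ = 100`
integrations. Default tolerances are rel 10⁻⁸ / abs 10⁻¹⁰ — tighter than
typical solver defaults because chaotic separation amplifies local error.
A stiff path (scipy LSODA with the analytic Jacobian) is available as
`solver_id="stiff"` and is compared against the compiled path by
`solver_crosscheck`. Dense interpolation onto the uniform grid preserves
adaptivity; the round-off band `x ∈ (−10⁻¹², 0)` is clamped to 0 for the
`x^0.5` terms, and anything below −10⁻¹² is a domain error.

### What pointwise solver agreement can and cannot show

On the limit-cycle attractor the two solver families track each other to
≈ 10⁻⁵ relative over tens of periods at default tolerances. Started from
`(1, 1, 1)`, however, *no* pair of integrators agrees pointwise at
`τ = 100`: the oscillation onset out of the unstable focus (τ ≈ 5.5) is
exponentially sensitive, so tolerance-level differences become an O(1)
phase offset — the same Dormand–Prince scheme at rel 10⁻⁸ vs 10⁻¹⁰
disagrees with itself by ~20% pointwise. The cross-check is therefore
performed from an on-attractor initial state; full-protocol runs are
required to agree in every phase-invariant statistic (classification,
K, ApEn, section counts) rather than sample-by-sample.

## Indicators

**0–1 test (correlation variant).** For an angle `c`, translation
variables `p_c(n) = Σ_{j≤n} φ(j)cos(jc)`, `q_c(n) = Σ φ(j)sin(jc)`
(j from 1). Finite-sample mean-square displacement
`M(n) = (1/(N−n)) Σ_j d(j,n)²` over the `N−n` available displacements
(the printed definition is the `N → ∞` limit; the bias of the
finite-sample divisor vanishes for `n ≤ N/10`), mean-corrected to
`D(n) = M(n) − E(φ)²(1−cos nc)/(1−cos c)`, and
`K_c = corr((1..n_cut), (D(1)..D(n_cut)))` with `n_cut = ⌊N/10⌋`. The
output is `K = median(K_c)` over `n_c = 100` angles drawn uniformly from
`(π/5, 4π/5)` — angles near 0, π, 2π resonate and are avoided; a
constant (zero-variance) displacement vector returns `K_c = 0` since a
constant signal is regular. K is invariant (±0.05) under the angle seed
and under amplitude scaling of the signal.

**Approximate entropy.** `ApEn = Φᵐ(r) − Φᵐ⁺¹(r)` with `Φᵐ(r)` the mean
log fraction of m-length embedded vectors within Chebyshev distance `r`,
self-matches included (every count positive, ApEn ≥ 0). Defaults
`m = 2` (the canonical embedding choice) and `r = 0.1` interpreted on the
standardized signal — i.e. 0.1 standard deviations — which makes ApEn
invariant under affine transformations of the observable; a raw-scale
threshold is available. ApEn runs on the same stride-100 series as the
0–1 test: the full 200,001-sample window is quadratic-cost prohibitive
and adds nothing at this sampling density.

**Lyapunov spectrum.** Benettin tangent-space integration: three tangent
vectors advected by the analytic Jacobian, re-orthonormalized by modified
Gram–Schmidt every 0.005 τ, exponents averaged over `[80, 500]` τ (the
running estimates are still settling at τ = 100, hence the long horizon;
both knobs are config). The renormalization cadence matters unusually
much for this flow: the contracting exponent is ≈ −690 per unit τ
(≈ −465 on the period-2 cycle) while the expanding one is ≈ +3.4, so
numerical cross-contamination of the frame grows like
e^(spread × interval) between QR steps, and during the relaxation spikes
the local contraction transiently exceeds what double precision can
represent across a segment — the third vector then collapses into the
span of the first two. Short segments keep the collapse events rare; when
one still occurs, the third direction is rebuilt exactly orthogonal (cross
product) and its recorded stretch floored at the representable residual.
Internal consistency is enforced by the sum rule
`L₁+L₂+L₃ = ⟨trace J⟩` along the attractor (holds to < 1%, asserted at
5%) and by invariance under halving the renormalization interval.
Exponents are reported per unit dimensionless time τ.

**Sections, peaks, spectra.** The Poincaré plane is coordinate `x` at the
midrange `(min+max)/2` of the kept window, both crossing directions,
crossings located by linear interpolation; distinct points are
single-linkage clusters at radius `tol × attractor diameter`, with the
counts stable for `tol ∈ [10⁻³, 10⁻²]` in the periodic regimes. (At the
kept-window *mean* level two branches of the period-2 loop nearly
coincide and the count degenerates from 4 to 3 — the midrange level is
the convention under which a simple loop yields exactly 2 points and the
period-doubled loop 4.) Local maxima use the strict-rise/level-fall rule
`s(k−1) < s(k) ≥ s(k+1)` (plateaus count once, at their first sample).
Amplitude spectra are one-sided FFTs of the mean-removed, Hann-tapered
signal (the kept window holds a non-integer number of periods),
normalized by the window gain and checked against Parseval's identity.

## Sweeps and zooms

A sweep computes one indicator record per grid point, each point fully
independent: the per-kf random seed is derived from (global seed, grid
index), so results are identical regardless of evaluation order, and a
partial table can be resumed without recomputation. Per-point failures
are recorded in an `error` column, not fatal. The desk-scale default is
201 points over (3×10⁻⁴, 5×10⁻⁴) — the full 10⁻⁷-step grid (2,001
points) sits behind `--full` and needs correspondingly more CPU; the
regime-interval structure is already resolved at the coarser grid. The
Lyapunov column is off by default in sweeps (it multiplies the per-point
cost ~20×) and always on for showcase analyses.

Classification: `K ≥ 0.5` ⇒ chaotic — the statistic is bimodal near
{0, 1}, so the midpoint is the unbiased cut; records with
`0.2 < K < 0.8` carry an additional unsettled flag, since intermediate
values indicate an orbit not yet on its attractor or an intermittent
regime. The nested zoom repeats the sweep on strictly contained
sub-intervals — (3×10⁻⁴, 5×10⁻⁴) ⊃ (3.25, 3.35)×10⁻⁴ ⊃
(3.322, 3.324)×10⁻⁴ — and reports the regular/chaotic mixture per level.

On the innermost interval the desk-scale pipeline finds K confined to
[≈0.48, 0.87]: intermittent values, almost all above the 0.5 cut. The
regular windows interleaved at that depth are narrower than a 101-point
grid spacing (a 401-point scan finds a single sub-0.5 point), so at desk
scale the innermost mixture can be one-sided — a resolution limit of the
grid, the τ = 100 window and the 0.5 cut acting on intermittent
statistics, not evidence against interleaving.

## Synthetic validation signals

Every indicator is exercised on series whose class is known a priori:
sines and multi-harmonic combs (regular; generated with a positive offset
so the mean-correction term of the 0–1 test is active), logistic-map
orbits at r = 3.2 (period-2, regular) and r = 4.0 (chaotic; the map
iterates from s₀ = 0.4 with 1,000 burn-in steps), and uniform white noise
(maximally irregular; the 0–1 test and ApEn both flag it "chaotic" — the
test detects diffusive (p,q) growth, not determinism). All generators are
seeded and bit-reproducible. These fixtures emulate the *statistical*
signatures the indicators respond to; they do not emulate relaxation-
oscillation waveforms, solver error, or intermittency, so passing them
validates the indicator implementations, not the reaction model itself —
that is what the showcase and sweep checks are for.

## Known limitations

- The desk-scale grids (201-point sweep, 101-point zoom levels) resolve
  the interval structure of the regime map but not windows narrower than
  the grid spacing.
- ApEn and K are computed at one sampling stride; both drift if the
  stride is pushed far from map-like density (tested sensitivity, not a
  bug).
- The 0–1 test yields intermediate K for intermittent orbits; such
  records are flagged rather than resolved (longer windows would be
  needed).
- Exponent values are tied to the τ convention through T₀; compare
  magnitudes across conventions by rescaling with T₀.
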