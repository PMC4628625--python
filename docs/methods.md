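# Methods

## Model

The package implements a fractal description of an anomalously diffusing
particle's trajectory.  The microscopic picture is a chain of straight
segments of equal length λ (the mean free path), each traversed at constant
speed in the Brownian step time τ, so the mean velocity along the path is
v₀ = λ/τ.  Observed at scale s, the trajectory has a scale-dependent
fractal dimension

    D_w(s) = D_w − (D_w − 1)/(1 + s/(kΛ)),        Λ = √(3/2)·λ,

which equals 1 (a line) below the mean free path and approaches the
asymptotic dimension D_w = 2/α at large scales.  α is the anomalous
diffusion exponent: D_w = 2 (α = 1) is ordinary Brownian motion, D_w > 2
(α < 1) a contracted, sub-diffusive path, D_w < 2 (α > 1) a stretched,
super-diffusive one, and D_w = 1 (α = 2) ballistic motion.

Integrating the fractal length relation d ln L/d ln s = 1 − D_w(s) gives
the displacement-to-contour ratio r/L(0) = (1 + r/kΛ)^−(D_w−1) and, setting
L(0) = v₀t, an implicit equation for the 2D MSD at any time:

    x·(k + x)^((2−α)/α) = k^((2−α)/α)·(t/τ),      x = √⟨r²⟩/λ.

Its short-time limit is ballistic, ⟨r²⟩ = (v₀t)², and its long-time limit
is ⟨r²⟩ = k^(2−α) λ² (t/τ)^α.  The crossover constant is fixed at k = 2,
the unique value for which the α = 1 case reduces to the standard
⟨r²⟩ = 4Dt with D = λ²/2τ; k is nevertheless kept as an explicit parameter
so the scale-dimension generalization remains testable at other values.
With k = 2 the transport coefficient and its closure are

    Γ = 2^(−α) λ²/τ^α,     Γ/D = (2τ)^(1−α),     Γ/D·τ^(α−1) = 2^(1−α).

The last identity is the universal-coordinate form on which systems with
different characteristic times collapse to a single curve.

An exact algebraic consequence of the solution, used as a test invariant,
is the partition identity

    (√⟨r²⟩/(v₀t))^(α/(2−α)) + (⟨r²⟩/4Γt^α)^(1/(2−α)) = 1,

which splits the advancement of the motion into its ballistic and
diffusive shares at every time.

Assumptions worth stating: the medium is statistically homogeneous on the
scale of a trajectory (one α, one Γ); the segment picture ignores waiting
times and trapping-time distributions, so ergodicity breaking and aging are
outside the model; all quantities are ensemble/time-averaged MSD
descriptions, not single-step statistics.

## Parameters

| symbol | meaning | units | default / typical |
|--------|---------|-------|-------------------|
| λ | 2D mean free path | length (µm) | calibrated; ~0.056 µm for a lipid tracer |
| τ | Brownian step time | time (s) | λ²/(2D); ~4×10⁻⁴ s |
| α | anomalous exponent | — | in [0.05, 2]; 1 = ordinary diffusion |
| k | crossover constant | — | 2 (universality; do not change for fits) |

The core is unit-agnostic: any self-consistent length/time pair works; the
CLI documents µm and seconds as the conventional pairing.  α below 0.05 is
rejected: the exponent (2−α)/α then exceeds 39 and the implicit equation
stops being numerically meaningful.

Dimensional conventions: the canonical solution is 2D; 3D values use
⟨R²⟩ = (3/2)⟨r²⟩ and Λ = √(3/2)λ, 1D uses ⟨x²⟩ = ⟨r²⟩/2 by isotropy
(matching the 2Γt^α vs 4Γt^α prefactor conventions).  These constants live
in `params.MSD_DIM_FACTOR`.

## Estimators

The calibration chain mirrors experimental practice:

1. **λ from two points** (`estimate_lambda_two_point`): writing the α = 1
   crossover equation at two times and dividing eliminates τ, giving a
   closed form that is exact (not asymptotic) on model data.  The estimator
   is degenerate when the two points imply ballistic scaling
   (√msd ∝ t) and inconsistent (negative λ) when growth is slower than the
   diffusive branch allows; both raise typed errors.
2. **τ = λ²/(2D)** from the unobstructed diffusion coefficient.
3. **α (and Γ through the closure)** from obstructed MSD data, with three
   strategies exposed as scikit-learn estimators:
   - `SinglePointMSDFit`: α is the root of model(t; α) = msd, bracketed by
     a 40-node scan of [0.05, 2] and polished by Brent's method.  Requires
     the observation below the ballistic bound √msd < λt/τ.
   - `CalibratedMSDFit`: minimizes Σ(model/msd − 1)² over α alone.  The
     relative criterion was chosen because MSD values span decades (it is
     first-order equivalent to least squares on log-MSD); the objective is
     pre-scanned on a Δα = 0.05 grid before bounded refinement to 1e−8 in
     case it is not unimodal (unproven).  Γ is *not* free: the closure ties
     it to α, which is exactly what makes short series informative.
   - `FreeMSDFit`: joint (α, Γ) given only D.  Internally parameterized as
     (α, ln τ) with Γ = D(2τ)^(1−α) and λ = √(2Dτ): this is smooth at
     α = 1, where the velocity expression v₀ = 2√D(Γ/D)^(1/(2(α−1))) is
     singular, so no exclusion window around α = 1 is needed (the velocity
     form itself still raises there and the 2D/λ form must be used).
     A 25×25 coarse grid over α × ln τ seeds a Nelder–Mead refinement; a
     flat-objective flag is set when perturbing α by 0.05 leaves the
     objective unchanged to 1e−12 relative.

Ratio-based estimators for media with a normal-diffusion reference:
τ = ratio^(1/(1−α))·t/2 and Γ/D = ratio·t^(1−α), where ratio is the
anomalous/normal MSD ratio *at the same time* for the same species.  No
interpolation across times is offered — a shared time stamp is required —
to avoid inventing an interpolation scheme the data may not support.

## Numerical choices

- The implicit equation is solved in u = ln x.  After dividing out k^e the
  residual is f(u) = u − ln n + e·log1p(eᵘ/k) (n = t/τ, e = (2−α)/α),
  immune to overflow of (k+x)^e at any α ≥ 0.05 and n ≤ 10¹⁰ and free of
  cancellation at small n.  The bracket is analytic: f(ln n) = e·log1p(n/k)
  > 0 (the ballistic bound), and ln n − e·log1p(n/k) − 1 is below the root
  by construction.  Brent's method at machine-precision tolerance
  (rtol 8.9e−16, ≤ 200 iterations); t = 0 returns 0 without the solver;
  α = 2 takes the exact ballistic branch (exponent identically 0, avoiding
  0⁰ ambiguity).
- At α = 1 the equation is the quadratic x(2+x) = 2n, whose closed form
  x = −1 + √(1+2n) serves as an independent oracle in the tests (agreement
  to 1e−10 relative over six decades).
- The approach of the solution to its long-time power law is O(1/x), so
  "asymptotic agreement" tests use t/τ = 10¹⁰ with a 1e−3 relative band.

## Synthetic data

`generate_msd_series` draws the forward model with multiplicative
lognormal noise (unit mean, specified CV; lognormal keeps MSD positive at
any CV), optionally averaging n replicate factors per point to emulate an
ensemble of tracks.  One integer seed determines everything.

`generate_trajectory` is an explicit **stand-in**: the crossover model
prescribes no microscopic update rule, so the generator only targets
specific observable properties and is never used in the reproduction
script.  It emits equal segments of length λ and duration τ with
directions chosen by regime:

- α = 2: one common direction — exactly ballistic, TA-MSD = (v₀Δ)².
- α = 1: wrapped-Gaussian turning angles with mean cosine ρ = 1/3.  An
  equal-step walk with one-step directional memory ρ has long-time
  diffusion coefficient λ²(1+ρ)/(1−ρ)/(4τ); ρ = 1/3 makes this equal the
  model's D = λ²/2τ, so the two-point λ estimator can be exercised end to
  end on simulated tracks.  (A fully uncorrelated equal-step walk has
  TA-MSD exactly linear in lag, which makes that estimator degenerate —
  and no equal-step walk can follow the model at lag τ, where the model
  MSD is 0.54λ² but a length-λ step forces exactly λ².)
- other α: directions are unit-normalized pairs of fractional Gaussian
  noises (Davies–Harte synthesis) with Hurst index H = α/2, giving
  power-law directional memory and a long-lag TA-MSD exponent near α.

An `oversample` option records positions along segments (the particle
moves at constant speed within a segment), resolving the sub-τ ballistic
regime.  What passing trajectory tests show about real data is therefore
limited: exponent targeting and the ordinary-diffusion calibration chain
are exercised; intermediate-lag shape fidelity to the crossover equation
is *not* claimed, and real-data features such as localization noise,
motion blur, and finite-track statistics are absent.

`msd_from_trajectory` is the standard time-averaged MSD over all start
points; it requires lags that are multiples of the sampling interval and
within the track's span.

## Problem sizes

The test suite and reproduction script run on one CPU in well under a
minute: the printed-value computations are single closed-form evaluations
or root solves; the recovery studies use 100–200 seeded replicates of 4–17
point series; trajectory checks use 10⁴-step walks (5 seeds for the
end-to-end calibration check, lags τ/10 and 300τ chosen a priori as deep
ballistic/deep diffusive).

## Known limitations

- The model is phenomenological: a single (α, Γ) pair per dataset, no
  trapping-time distributions, no ergodicity breaking, no confinement
  plateaus, no directed-motion drift beyond the α = 2 limit.
- The least-squares criterion (relative residuals, equal weights) is a
  design choice; heteroscedastic tracking noise might justify other
  weights.  It is isolated in the estimator classes and straightforward to
  swap.
- Printed-value reproductions inherit the rounding of their inputs: with
  λ = 0.0559 µm and D = 4.15 µm²/s, τ computes to 3.765×10⁻⁴ s (printed
  3.77×10⁻⁴), and the short-time normalized MSDs computed with the rounded
  printed Γ differ by ~0.003 from the printed 0.803/0.608.
- The free fit needs data spanning enough of the crossover to separate α
  from τ; on pure power-law data the objective is flat in the
  parameterization and the result carries a warning flag.
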