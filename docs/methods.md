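# Methods

## Model and conventions

The walk is a discrete-time lazy nearest-neighbor random walk on a finite
d-dimensional box with 1-based site indices.  The d-dimensional operator is
the arithmetic mean of d one-dimensional operators on the tensor-product
space: per-neighbor jump `q_i/(2d)` in dimension i, staying probability
`1 − (1/d) Σ q_i`.  This is the unique nearest-neighbor convention consistent
with both the 1D statement (per-neighbor `q/2`) and the reference 2D values
(jump 0.05, stay 0.8 at `q = (0.2, 0.2)`), and it makes the spectral
decomposition exactly separable.  A second kernel (`kernel="product"`, the
tensor *product* of the 1D operators) describes two particles moving
simultaneously — a next-nearest/diagonal-move walker — and is used by the
coalescence scenario.

Boundaries per dimension: reflecting (blocked jumps fold back into the
staying probability — confirmed by MFPT(1→2, q=1) = 2, which requires stay
1/2 at the boundary site), periodic, or absorbing at one or both faces.  An
absorbing site swallows the walker on arrival; its row and column are removed
from the dynamics, and the propagator is identically zero there.  The
one-sided absorbing kinds leave the opposite face reflecting.

Defect pairs store resolved numeric λ values.  Validation bounds every
λ against the *conserving flow template* (the operator assembled without
removing absorbing rows/columns), so barriers modulating an absorption flux
are admissible; `apply_defects` then treats a λ on a transition into an
absorbing site as an adjustment of the implicit leak (only the active
endpoint's staying probability is stored).  Pair uniqueness is enforced on
unordered site pairs; duplicates raise rather than merge.  For sticky and
slippery sites, k counts the site's actual neighbors (reflecting boundaries
reduce k; an adjacent absorbing site does not count), which keeps the
staying-probability constraint automatic.

## Propagators

The homogeneous generating function is evaluated through the exact
eigendecomposition of the symmetric transition operator:
`φ̃_{n0}(n, z) = Σ_k ψ_k(n) ψ_k(n0) / (1 − z σ_k)`.  For face-wise absorbing
structure the decomposition stays a product of per-dimension decompositions
(cosine-type for reflecting, Fourier for periodic, sine-type for absorbing
faces — obtained numerically per dimension, which is exact to machine
precision and uniform across boundary kinds); individually absorbing sites
break separability and trigger a dense decomposition of the restricted
operator.  Since the eigen-sum is the exact rational continuation of the
series, evaluation is refused only *on* a pole `1/σ_k` — this is what allows
derivatives of pole-free ratios at z = 1 on conserving lattices.

The defect correction is computed as `Φ̃ = φ̃ − gᵀH⁻¹c` (matrix determinant
lemma applied to the rank-one corrected determinant ratio), with a pivoted LU
solve and an explicit log-determinant-ratio fallback if the factorization is
unreliable.  A `DefectSystem` caches the eigenbasis rows of all defect sites,
so one evaluation point costs one M×M solve.

## Series inversion

Time-domain probabilities come from the radius-corrected inverse DFT on
`K = 4(T+1)` points of the circle `r = eps^{1/(T+1)}`.  Aliasing is damped by
`r^K = eps^4` while round-off in the FFT is amplified by up to `1/eps`; with
the default `eps = 1e-4` the two balance at ~1e-11 absolute error for
horizons of a few hundred steps (an `eps` as small as 1e-8 would push
round-off amplification to ~1e-8, visibly above the 1e-10 agreement the
oracle-equivalence tests demand).  Coefficients must be real within 1e-8 and,
for probability series, inside [0, 1] within the same tolerance before being
clamped; violations raise with diagnostics rather than being silently
repaired.

## Means

* **MFPT / MET** — survival sum `S̃_{n0}(1) = Σ_m Φ̃_{n0}(m, 1)` with the
  target (and any absorbing boundary) built into the homogeneous propagator
  first, then the inert defects added through the defect correction.  With
  absorption present, z = 1 is a regular point and no limit is needed.
  Sealed regions (impenetrable enclosures, fully sticky traps) would make H
  singular at z = 1 — the enclosed conserving subsystem contributes a unit
  eigenvalue — so sites unreachable from the source under the *perturbed*
  dynamics are marked absorbing in the homogeneous propagator beforehand.
  This is exact: the impenetrable defect pairs cancel the spurious leak, and
  pairs with one absorbed endpoint reduce to their one-sided part because the
  propagator vanishes there.  Configurations whose passage is not certain
  (detected by reachability analysis on the perturbed operator) return
  `inf` together with the hitting probability, never NaN or an exception.
* **MRT** — Kac's lemma `1/π(n)` on the stationary distribution of the
  perturbed operator; on a reducible chain the MRT is computed on the closed
  communicating class of the site (with a warning), and `inf` is returned
  for transient sites.  This reproduces the asymmetric-barrier piecewise
  closed form exactly.
* **Cross-check** — the MFPT is also computable as the z = 1 derivative of
  the renewal ratio (whose propagator poles cancel), by central differences
  with two Richardson levels from a base step `h = 1e-5`.  The step must
  satisfy `h · MFPT ≪ 1`; the default suits means up to ~1e4 steps and
  agrees with the survival route to ~1e-10 relative in the tests.

## Quasi-1D single-barrier closed forms

For a symmetric barrier λ between u and u+1 on the half-line with a
reflecting wall between 0 and 1, the first-passage generating function was
derived from the one-defect renewal ratio and simplified: with
`ζ = acosh[1 + (1/z − 1)/q]`, `A = e^{−ζ}`, `w = 2λ/q` and the barrier
response

    T(z) = w(1 − A)(A^{2u} − 1) / [w(2A + A^{2u}(1 − A)) − (1 + A)],
    G(m)  = 2 cosh[(m − ½)ζ] + 2 T sinh(uζ) e^{−(m − u − ½)ζ},

one has `F̃ = G(n0)/G(n)` for `u < n0` and
`F̃ = 2 cosh[(n0 − ½)ζ](1 − T)/G(n)` for `u ≥ n0`.  The form is verified to
~1e-15 against the defect solver over a grid of (u, λ, z) including the
impenetrable limit, and its derivative at z = 1 reproduces the mean
`F = (n − n0)(n + n0 − 1)/q + [2λ/(q(q/2 − λ))]·u·1{u ≥ n0}` — the disorder
indifference result: the mean is *independent of λ* whenever the barrier sits
behind the source, even though the distribution's mode and tail both grow.

## Oracles and what the tests show

Three independent routes validate every analytic quantity: direct iteration
of the perturbed Master equation (exact, the primary oracle, agreement
demanded to 1e-10 over t ≤ 200), absorbing-chain linear solves for means, and
a seeded Monte Carlo sampler.  The sampler evolves per-site walker *counts*
with multinomial redistribution — statistically identical to independent
trajectories but orders of magnitude faster — requires an explicit seed (no
silent default), counts first passage only from t ≥ 1, excludes censored
walkers from mean estimates and reports the censoring fraction.  For the
two-target comparison (1e5 walkers, t ≤ 300) the exact-null maximum
z-statistic over 301 correlated time points is ~3, so the agreement assertion
is "≥ 99 % of points within 3 binomial SE and none beyond 6 SE" rather than a
literal all-points bound.

Because all fixtures are lattice walks generated by the package itself, the
tests demonstrate internal exactness and the expected limit behaviors; they
do not calibrate against empirical movement data.

## Scenarios: geometry choices and problem sizes

* **Brick-and-mortar.**  Bricks of (height, width) sites are sealed by
  barrier pairs on their outline edges, separated by one-site mortar
  channels (periods height+1 and width+1; the periodic width must be a
  multiple of width+1), staggered by half a period per layer, stacked from
  the row above the absorbing face; edges into the absorbing face carry no
  barrier (nothing returns from there, and the sealed interiors remain
  unreachable).  The puncture removes every pair with an endpoint inside the
  h×w rectangle anchored at the top boundary and centered on the start
  column.  Tests run the impenetrable case at 13×12 (bricks 3×5) where the
  interior MET maximum and oscillation are already present, and the
  permeable α = 0.9 case at the full 37×36 geometry — at 13×12 the monotone
  decrease carries a ~0.2 % discretization bump, an artifact of a 3-layer
  pattern.
* **Thigmotaxis.**  A lattice edge carries a barrier iff its endpoint site
  centers lie on opposite sides of the circle (Euclidean distance to the
  domain center; sites with d ≤ radius count as inside).  The outer circle
  is impenetrable; inner-circle edges are one-way (outward free, inward
  reflected with probability α_i).  The steady-state MSD uses the limiting
  distribution of the perturbed chain — on reducible chains the closed
  communicating classes reachable from the start, weighted by absorption
  probability.  Tests use a 25×25 arena (R = 11, r = 6 or 9) where the
  saturation ordering in r/R is resolved.
* **Coalescence.**  On the product-kernel lattice, off-diagonal↔diagonal
  edges carry `λ = α_e A` against binding and `λ = (1 − α_u) A` against
  unbinding, diagonal↔diagonal edges `λ = (1 − α_c) A`, and the
  side-swapping edges (m+1, m)↔(m, m+1) symmetric `λ = α_e A` so that full
  exclusion also forbids crossing without meeting.  This placement realizes
  all four limit behaviors exactly (free walk at (0, 1, 1), irreversible
  binding at α_u = 0, immobile complex at α_c = 0, no meeting at α_e = 1)
  and the cohesive-mobile-quadrant minimum of the MFPT ratio map.  Tests run
  N = 12 with the target at the segment end and maximally separated
  particles.  Known limitation: the narrative feature that at very small
  α_c an *intermediate* α_u minimizes the MFPT does not appear with this
  placement at N ≤ 30 (the minimum sits at α_u = 1); it is not asserted.

## Other limitations

Continuous-time dynamics, biased homogeneous walks, non-nearest-neighbor
homogeneous kernels, cover times, resetting and mortal walkers are out of
scope.  The generic M×M defect matrix is used even for sticky/slippery sites
(no 2d-fold size reduction); correctness is preferred over this
micro-optimization at the problem sizes the package targets (lattices up to
a few thousand sites, M up to ~1e3).
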