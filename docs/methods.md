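# Methods

## Model and stochastic construction

The package implements the nondimensional Rosenzweig–MacArthur system
with Holling type II predation on the state space Q = [0, ∞)², with the
open quadrant D = (0, ∞)² as the ambient domain of the diffusion
formulations.  Equilibria are K1 = (0,0), K2 = (k,0) and, when `m > c`
and `k(m−c) > c` (both strict), the coexistence state
K3 = (c/(m−c), (k(m−c)−c)/(k(m−c)²)).  At feasible K3 the Jacobian
determinant is positive, so stability is decided by the trace; the trace
changes sign at k_H = (m+c)/(m−c), which partitions parameter space into
the stable regime Λ2 (k < k_H) and the oscillatory regime Λ1 (k > k_H).
`classify_regime` reports "threshold" when |k − k_H| ≤ 1e−12·k_H.

The stochastic layer is built once, generically: a `ChannelSystem` pairs
a stoichiometric matrix S (columns ν_k) with intensity functions f(x),
and everything second-order follows from

- drift b(x) = S f(x),
- diffusion covariance a(x) = (1/Ω) S diag(f(x)) Sᵀ,
- count-level propensities λ_k(X) = Ω f_k(X/Ω).

`ChannelSystem.custom` accepts arbitrary (S, f) pairs (tested with a
three-species food chain whose trophic couplings produce a banded
covariance), but only the Holling-II intensities ship built-in.

### Closures

Three drift-compatible predation representations are provided:

| closure    | predation columns      | predation covariance block (×f_pred/Ω) |
|------------|------------------------|----------------------------------------|
| bernoulli  | (−1,+1) @ e·f_pred, (−1,0) @ (1−e)·f_pred | [[1, −e], [−e, e]]  |
| effective  | (−1, e) @ f_pred       | [[1, −e], [−e, e²]]                    |
| split      | (−1,0) @ f_pred, (0,+1) @ e·f_pred        | [[1, 0], [0, e]]    |

with f_pred = mNP/(1+N).  The bernoulli closure is the exact
integer-valued mechanism (predation encounter followed by Bernoulli
conversion with success probability e); the effective closure is its
compact diffusion-level aggregate — identical cross-covariance, predator
variance e² instead of e (jump sizes enter covariances squared); the
split closure is the drift-matched diagonal-noise comparator.  At the
reduced baseline e = 1 (the package default, matching the deterministic
backbone's parameterization) bernoulli and effective coincide.  The SSA
refuses the effective closure categorically, even at e = 1 where its
column happens to be integer: it is a diffusion-level object by
construction.

State ordering is (prey N, predator P) everywhere, and channel ordering
follows the event list R1…R5 above, so all printed matrices match the
stoichiometric layout.  ρ is reported signed (a₁₂/√(a₁₁a₂₂)); callers
wanting the small-cross-covariance diagnostic use |ρ|.

## Exact CTMC simulation

`ssa_trajectory` implements the Gillespie direct method — exponential
waiting time at rate Σλ, channel chosen proportionally to λ_k — with no
tau-leaping; exactness is the module's purpose.  Extinction of one
species does not stop the run (the survivor's channels continue); only
the total-extinction state (0,0) has zero exit rate and freezes the
path.  Count states from densities are formed as round(Ω·x), half away
from zero.  Thinned recording interpolates by last observation carried
forward on a uniform grid (the paths are right-continuous step
functions).

`empirical_increment_moments` estimates E[ΔX] and Cov(ΔX) over
independent windows of length dt from a fixed state; windows are evolved
exactly (a vectorized direct method over the active windows), so the
estimates test the master-equation identities E[ΔX] ≈ Σλ_kν_k·dt and
Cov(ΔX) ≈ S diag(λ) Sᵀ·dt without discretization error beyond O(dt²).
A warning is raised when dt·Σλ > 0.1; fewer than 100 replicates are
rejected outright.

## Diffusion integration and boundary formulations

`em_step` advances x ← x + b(x)dt + Σ(x)√dt·z.  Two factorizations of
a = ΣΣᵀ are exposed: a 2×2 Cholesky root (default, two Brownian
drivers; at boundary states where a is singular an eigenvalue-clipped
symmetric root replaces it, since demographic intensities vanish there)
and the event factorization (1/√Ω) S diag(√f) with one driver per
channel, preserving channel semantics.  Both generate the same
covariance and hence the same diffusion law.

The **absorbed** formulation freezes the path at its first boundary
contact: the first Euler–Maruyama proposal with a nonpositive component
is projected (negative components set to 0), τ is the grid time of the
offending step — an O(dt) discretization of the first-exit time, with no
Brownian-bridge sub-step refinement — and the state is constant
thereafter.  If both components cross in one step the face is recorded
as "corner".  The **open-proxy** formulation instead raises any proposal
component below `clip_epsilon` to `clip_epsilon` and continues.  Clipping
at `clip_epsilon` (not merely at 0) keeps every output state a strictly
positive margin from the boundary, which is the point of the device; it
is a visualization proxy for survival-conditioned interior dynamics and
is never to be read as the continuous-time open-domain law.  With a
shared seed the two formulations consume identical noise per step and
coincide exactly until the first clipping event.

Defaults: dt = 1e−3, clip_epsilon = 1e−6, both config-exposed (no
canonical values exist for them; sensitivity is left to the user).
`record_stride` controls the recording resolution without affecting the
integration or the absorption logic.  The deterministic reference
integrates the vector field with scipy's adaptive RK45 at rtol 1e−8,
atol 1e−10.

### Random numbers

Replicate streams derive from `numpy.random.SeedSequence([seed,
replicate])`, so batches are order-independent and a longer batch
reproduces a shorter one as a prefix.  The jitted kernels seed numba's
internal RNG with a 32-bit state drawn from the same sequence; given the
seed, every path is bit-reproducible.

## Covariance geometry

Ellipses are drawn from the diffusion matrix a(K3) itself — the object
the closures disagree about — not from a stationary (linear-noise)
covariance; no Lyapunov equation is solved.  Semi-axes at σ-level s are
s·√(eigenvalues); the orientation is the angle of the leading
eigenvector mapped to (−90°, 90°], with ties reporting 0°.  Default
σ-levels are {1, 2}.  The ρ scan masks cells exactly where K3 is
infeasible, overlays k_H(m), and is Ω-invariant because the 1/Ω factor
cancels in the ratio.  Default scan resolution is 60×60 (config-exposed).
`empirical_state_covariance` conditions on survival: it uses grid times
after the burn-in and strictly before τ, and refuses paths absorbed
before the burn-in ends or with fewer than 10 usable points.

## Generator diagnostics

For the radial potential V = (1+N²+P²)^α (α > 2 enforced), `generator_V`
evaluates ℒV = ∇V·b + ½tr(a∇²V) from the closed-form partial
derivatives, using the coupled (bernoulli) covariance; the closed-form
coefficients are cross-checked against the stoichiometry engine in the
tests, and an independent central-difference oracle
(`finite_difference_generator`, step h = 1e−4) agrees to a relative
1e−5 in float64.  The potential is a coercive radial abundance index — a
smooth proxy for distance from total extinction — not a conserved
biomass.

`verify_linear_growth` samples ℒV/(1+V) on log-uniform n×n meshes of
[1e−4, R]² for increasing radii R (probing near-boundary and
large-radius behavior at once) and reports an empirical constant
C_estimate for ℒV ≤ C(1+V).  Two numerical choices matter:

- **Divergence heuristic.**  For the R–M drift the per-radius maximum
  converges to its supremum (≈ 2α(m−c) along the large-P direction) but
  slowly, so raw growth between two radii is a poor divergence signal.
  The certificate therefore flags `violated` only when the slope of the
  per-radius maximum with respect to log-radius fails to decay *and* the
  maximum still grows beyond the tolerance (default 5%); with only two
  radii the simple relative-growth rule applies.  A super-linear drift
  (e.g. the test hook b = (N², 0)) keeps a non-decaying slope and is
  flagged.  This is a configurable diagnostic, not a proof.
- **Certificate polish.**  C_estimate is the grid maximum over the
  largest box refined by a Nelder–Mead search in log-coordinates started
  at the grid argmax, so off-grid states sampled later do not exceed the
  certified constant.

Only the anti-explosion potential is instantiated.  The boundary-barrier
stage of positivity invariance has no explicit closed-form barrier for
this model; `generator_value` accepts any user-supplied (V, gradient,
Hessian) triple so a barrier candidate can be certified the same way.

## Problem sizes used in the shipped experiments

The test suite and examples use: 1e5 windows for the increment-moment
check at X = (10,5), Ω = 10, dt = 1e−3; 100 absorbed replicates at
Ω = 150, k = 5.5, dt = 1e−3, t_max = 200 for the extinction experiment
(the paper-scale version of this experiment uses 300 paths; 100 suffice
for the qualitative claim that a nonzero fraction absorbs with a
nondegenerate time distribution); 50 SSA replicates at Ω = 5000 and 200
Euler–Maruyama paths at Ω = 1e4 for the mean-field consistency checks;
60×60 cells for the ρ scan at two system sizes.

## What the synthetic experiments do and do not show

All inputs are generated by the model itself — there is no external
data.  Passing tests therefore certify internal consistency: that the
simulators sample the laws the formulas define (waiting-time and moment
identities, mean-field limits, factorization equivalence) and that the
structural claims (sign of a₁₂, drift/covariance non-equivalence,
boundary contracts, generator bounds) hold over the sampled parameter
ranges.  They do not validate the R–M model against field data, and the
diffusion results inherit the usual chemical-Langevin caveats: the
approximation degrades at very small counts, exactly where the absorbed
formulation's boundary behavior is read off, so extinction times from
the diffusion are regime-level diagnostics rather than quantitative
predictions of the CTMC's.  The Euler–Maruyama absorption time is an
O(dt) overestimate of the true first-exit time (no sub-step crossing is
detected), and the open proxy's behavior near the boundary depends on
the unphysical parameter `clip_epsilon`.

## Known limitations

- No tau-leaping, hybrid switching, or direct CME solves; the SSA is the
  only count-level integrator.
- No Milstein or higher-order SDE schemes, no exact boundary-hitting
  bridges, and no reflected/conditioned (Doob h-transform) construction
  of the true open-domain law.
- Power spectra / quasi-cycle peak analysis and stochastic sensitivity
  machinery are out of scope.
- The generator certificate is empirical: it exhibits a constant and a
  saturation trend, not a symbolic bound.
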