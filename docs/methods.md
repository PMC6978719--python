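# Methods

## Scope and model

`icas-hemoflow` reproduces, at desk scale, a hemodynamic analysis of focal
intracranial atherosclerosis: steady blood flow through a stenosed middle
cerebral artery (MCA) segment, wall shear stress (WSS) and wall pressure
measured at five defined points along the lesion's prominent-side wall, the
translesional (FFR-like) indices derived from them, and nonparametric
statistics over a lesion cohort.

Patient imaging is replaced by a parametric lesion model.  The full 3-D
patient-specific problem is reduced to the axisymmetric meridian plane
(r, z) — the reduction preserves exactly the quantities the measurement
scheme uses, WSS and wall pressure along one longitudinal wall section —
plus an optional 2-D planar channel mode for eccentric (one-sided)
plaques.  Everything downstream of the solver (five points, indices,
statistics) is independent of this choice.

Blood is an incompressible Newtonian fluid with density ρ = 1060 kg·m⁻³
and dynamic viscosity μ = 3.5 × 10⁻³ Pa·s.  (The density is occasionally
printed elsewhere with inconsistent units; we use the standard
1.06 g·cm⁻³.)  Flow is steady and laminar; cases whose throat-jet Reynolds
number Re_jet = 2ρQ/(πr_throat μ) exceeds a configurable cap (default
2000) are refused as out of regime rather than solved unreliably.

## Geometry

A lesion is a cosine bump on an otherwise straight tube: fractional lumen
reduction f(z) = (s/2)(1 + cos(2π(z − z₀)/L)) for |z − z₀| ≤ L/2, where
s is the WASID diameter-loss fraction, L the lesion length and z₀ the
throat position.  The profile is C¹ at the lesion edges and reaches
severity s exactly at the throat; WASID percent stenosis
(1 − D_stenosed/D_reference) × 100 applied to the discretised lumen
recovers the specified severity to < 0.1 percentage points.  Real plaques
are irregular; the smooth bump is the standard stenosis-benchmark shape
and the price of having no imaging.

Vessels keep at least five unstenosed reference diameters on both sides of
the lesion.  The pipeline default is 6 diameters upstream and 30
downstream: the long run-out lets the post-stenotic jet relax before the
outflow boundary, which both stabilises the solve and keeps the
inflow-vs-outflow mass check meaningful at high severities.

In planar mode a one-sided plaque removes lumen from a single wall; beyond
50% diameter loss such a wall legitimately crosses the centreline, so the
planar representation stores signed wall positions and requires only a
positive residual gap.  The prominent side is the wall contributing more
to the narrowing (ties toward the upper wall).

Lesion entrance/exit are operationalised as the first/last axial positions
where the relative lumen deficit crosses a threshold (default 2%,
linearly interpolated between samples); the apex is the sampled position
of minimum lumen.  The original study identified these points on images;
a deficit threshold is our deterministic equivalent.

## Flow solver

Stream-function/vorticity form of the steady incompressible Navier-Stokes
equations on a wall-fitted structured grid (transverse coordinate
η = distance between walls, mapped by the chain rule; tanh clustering
toward no-slip walls, wall spacing ≈ 0.15× uniform; axial nodes clustered
around the lesion by a Gaussian density bump so long run-outs do not
starve the lesion of resolution):

* E²ψ = −rω (axisymmetric) or ∇²ψ = −ω (planar),
* u·∇ω − (u_r/r)ω = ν(∇²ω − ω/r²).

Boundary conditions: a *discretely* fully developed inflow — the
straight-tube solution of the same transverse stencils, computed from a
1-D two-point problem — carrying exactly Q = mean velocity × inlet area
with mean velocity = PSV/3 + 2·EDV/3; no-slip walls; zero-gradient
outflow.  No-slip is imposed directly: the vorticity-slot row at each wall
node enforces ∂ψ/∂n = 0 with a one-sided stencil, and the wall vorticity
is determined implicitly by the coupled system.  (The classical Thom wall-
vorticity update divides an O(Δ²) stream-function difference by the
squared wall spacing; on wall-clustered grids that catastrophic
cancellation amplifies iteration noise enough to prevent convergence, and
was abandoned after measurement.)

The two fields are solved fully coupled.  A short under-relaxed Picard
phase on the first-order upwind operator provides a warm start; damped
Newton iterations (analytic Jacobian, line search) then converge the
target scheme quadratically.  Advection is a blend of second-order central
(weight `central_weight`, default 1.0) and first-order upwind.  Strong
jets are reached by adaptive continuation in flow rate (coarse steps,
halved on failure, regrown on success, each level warm-started from the
rescaled previous state).  All linear systems are column-scaled by the
field magnitudes (ψ ~ 10⁻⁶ m³/s vs ω ~ 10³ s⁻¹) and row-equilibrated
before the sparse direct solve; without this the direct solver loses the
wall shear information to roundoff.  Convergence is declared when the
root-mean-square row-equilibrated residual falls below
`convergence_tolerance` (default 10⁻⁶); non-convergence raises an error
carrying the final residual.

Axial velocity is evaluated as u = (2/h²)·dψ/d(η²), which is regular on
the axis and exact for developed profiles — avoiding the 1/r noise
amplification of the naive (1/r)ψ_r form near the centreline.

Default grid: 256 axial × 48 transverse cells; a straight tube then
reproduces the Poiseuille pressure drop and wall WSS to ≈ 0.15%, and
≈ 0.04% at doubled resolution.  Incompressibility is exact by
construction; the reported mass-conservation error is the relative
imbalance of the numerically integrated inflow and outflow profiles.

Pressure is recovered after convergence in two steps.  Wall pressure —
the measured quantity — comes from integrating the tangential momentum
balance along each no-slip wall (dp/ds = μ(∇²u)·t; the advective terms
vanish at the wall), which keeps discretisation noise near a strong jet
local: a global Neumann-Poisson solve in a long thin tube instead converts
any local flux inconsistency into a spurious axial gradient across the
whole vessel, which we observed at throat-jet Reynolds numbers ≳ 1500 and
eliminated this way.  The interior field then solves the pressure Poisson
equation with those wall values as Dirichlet data, the uniform inlet plane
as reference, axis regularity, and an axial-momentum Neumann outlet.  The
absolute level is anchored so that the
inlet-plane mean equals the mean arterial pressure
MAP = diastolic + (systolic − diastolic)/3 (1 mmHg = 133.322 Pa), making
the terminal/origin pressure ratio an absolute FFR-like index; an optional
linear resistance outlet (P_out = P_d + R_d·Q) anchors downstream instead.
WSS is μ|ω| at the wall, which at a rigid no-slip wall equals the
tangential traction magnitude.

## Measurement scheme

Five points on the prominent-side wall: origin and terminal (lesion
entrance/exit), apex (maximal encroachment), and the arc-length midpoints
M_up and M_down of the upstream and downstream sections.  Point values are
linearly interpolated between profile samples; extrema are taken over the
sampled profile restricted to [origin, terminal], with ties broken toward
the most upstream position (deterministic, resolution-controlled — no
sub-sample optimisation).  An extremum within 2% of the lesion length of a
named point is labelled with that point, otherwise with its enclosing open
section; the tolerance is a convention of this package.  Derived indices:
WSS ratios max/origin and min/origin, pressure ratio terminal/origin,
total pressure drop origin−terminal and its four segment contributions
(which sum to the total identically).  A zero origin value makes the
normalised ratios undefined; they are reported as NaN while the absolute
indices remain.

Exclusion rules are applied before solving: tandem lesions with a
neighbour closer than 2 cm and lesions at a bifurcation/branch opening are
excluded with machine-readable reasons; per-case solver failures (regime
cap, non-convergence) are likewise recorded as exclusions, never silently
dropped.

## Synthetic cohort

The generator emulates the study population: WASID percent stenosis
~ Normal(43.2, 17.3²)% clipped to [10, 85]%; lumen radius
~ Normal(1.5, 0.15) mm; PSV ~ Normal(0.9, 0.2) m/s with
EDV = PSV·Uniform(0.3, 0.6); blood pressure 130/80 ± (15/10) mmHg; age
~ Normal(65.5, 8) years; male with probability 0.545; plaque side
upper/lower/both with probabilities 0.4/0.4/0.2; tandem-lesion and
bifurcation flags Bernoulli(0.1) each, with flagged tandem distances
~ Uniform(0.5, 4) cm so the 2 cm rule bites on a subset.  Lesion length —
stated nowhere in the source material — is Normal(8, 1.5) mm clipped to
[4, 12] mm, a typical M1-segment plaque footprint.  Only the stenosis
moments, mean age and sex ratio are study-anchored; everything is
overridable through the `population:` config block.

All randomness derives from one root seed split into named substreams
(stenosis, geometry, velocity, pressure, covariates, flags), so changing
one variable's parameters never perturbs another's draws, and a fixed
(n, seed, population) reproduces the cohort bit for bit.

What the generator does **not** emulate: irregular plaque morphology,
correlated multi-lesion anatomy within a patient (lesions are sampled
independently; the analyses also treat them as independent units, a caveat
shared with the source analysis), velocity-severity coupling (inlet
velocities are drawn independently of severity, so extreme stenoses keep
their nominal flow rather than autoregulating down — translesional drops
at ≥ 70% are therefore larger than clinically observed ratios), and any
imaging/measurement noise.  Passing cohort tests therefore demonstrates
that the *pipeline* recovers the qualitative structure (extremum
locations, monotone and threshold-like severity trends, tight
WSS_max-pressure-drop coupling), not that the synthetic numbers match
patient values.

## Statistics

Implemented from their defining formulas with average ranks for ties:
Spearman rank correlation (p from the t approximation, optional exact
enumeration or seeded Monte-Carlo permutation), partial Spearman
(rank-residualisation on covariate ranks; our reading of "adjusted by age
and sex", which the source does not specify; sex enters as 0/1), the
Friedman test with tie correction (χ² tail or vectorised within-block
permutation null), Bonferroni adjustment, Wilcoxon signed-rank (zeros
dropped; exact dynamic-programming null for n ≤ 25 without ties, normal
approximation with tie correction otherwise) as the post-hoc after
Friedman, Pearson's chi-square test of independence, and Cohen's kappa.
Two-sided p-values, α = 0.05.  A variable fully explained by the
covariates has partial correlation 0 by convention (the residual is
numerical noise).  The severity-split analysis runs the adjusted
correlation separately below/at-or-above the 50% cutoff and requires at
least 5 lesions per subgroup.

The pipeline's kappa compares two severity classifications (specified vs
geometry-recovered ≥ 50%) as a stand-in for the original inter-observer
agreement, for which no second rater exists here.

## Problem sizes and defaults

The shipped study replica uses n = 55 lesions at the default grid; a full
run (sampling, exclusions, ~47 flow solves, measurement, statistics)
completes in a few minutes on one core.  Severity sweeps use a fixed
template vessel (R = 1.5 mm, L = 8 mm lesion, PSV/EDV = 0.40/0.16 m/s,
130/80 mmHg): a moderate physiological flow chosen once so that the whole
20-80% sweep stays inside the laminar steady regime and the outlet profile
remains resolvable at 80%.

## Known limitations

* Steady flow at the time-averaged rate: no pulsatility, so no oscillatory
  shear metrics; the single-valued indices are the target quantities.
* Rigid walls, Newtonian rheology, single straight vessel — no circle-of-
  Willis network effects or collateral flow.
* The lumped-parameter outlet of the original solver is unrecoverable; the
  default reference-pressure anchoring reproduces the FFR-like ratio
  semantics, and a linear resistance outlet is provided as the
  lumped-model stand-in.
* Axisymmetric (or planar) reduction: out-of-plane plaque morphology and
  secondary flows are absent.
* At severities ≳ 70% with fixed inlet flow the computed drops exceed
  clinically plausible translesional ratios (see the velocity-severity
  note above); trend-level conclusions are unaffected.
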