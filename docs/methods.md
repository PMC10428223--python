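# Methods

## Permeability model

The barrier is the intercellular lipid matrix of the stratum corneum,
modelled as N identical bilayers in series (default N = 30, the cryo-EM
based estimate 30 ± 6; K_P scales as 1/N, so relative quantities such as
enhancement ratios are independent of it). For one bilayer the
inhomogeneous solubility–diffusion resistance is

    R = ∫ exp(β ΔG_transfer(z)) / D(z) dz,

integrated by the trapezoidal rule over the full sampled grid (no
extrapolation beyond it). ΔG_transfer is referenced to the permeant's
solvation free energy in the donor formulation, which is what makes K_P a
formulation-dependent quantity. Temperature defaults to 305.15 K (skin
surface conditions); β = 1/RT ≈ 0.394 mol/kJ, RT ≈ 2.537 kJ/mol. The unit
bridge is exact: 1 nm/ps = 3.6 × 10⁸ cm/h.

Numerical choices:

- The diffusion profile is resampled onto the PMF grid by linear
  interpolation, never the reverse, so the exponential of the free energy
  — the stiff factor — is evaluated only at sampled points.
- Quadrature error: on smooth profiles the trapezoid converges at second
  order (checked by grid-refinement tests); on piecewise-constant test
  profiles with boundaries represented in the grid it is exact, which is
  how the closed-form oracle 1/K_P = N·Σ Lᵢ e^{βGᵢ}/Dᵢ is matched to
  ~1e-10 relative error.
- Uncertainty: when a per-point PMF standard error is available (e.g.
  from replicate averaging), K_P is recomputed on the ΔG ± σ(z) envelopes
  and half the spread in log₁₀K_P is reported. This is deliberately
  conservative (it treats the error as fully correlated along z); the
  less conservative alternative — propagating independent per-point
  errors through the integral — would require the full covariance of the
  sampled PMF, which bias-sampling estimators do not provide.

## Profile preprocessing

Raw adaptive-bias outputs are repaired in a fixed order: (optional)
mirror symmetrization about the bilayer midpoint, edge repair, min-shift.
Friction profiles are inverted to D(z) = 1/g(z) and then smoothed with a
0.2 nm rolling median (median, not mean, because friction-metric noise is
spiky and heavy-tailed). Edge repair replaces the first and last two grid
points with their nearest interior value — on the 0.01 nm grid used here
those are the points at 0.005/0.015 and 5.200/5.210 nm — because
symmetrized sampling leaves artificial spikes there. The PMF is then
shifted so its minimum is ≥ 0; the shift is recorded in metadata, and a
shifted profile is permanently marked: the flux-design classifier refuses
it, since the min-shift erases exactly the formulation-reference
information that classifier needs. Whether symmetrization applies to the
friction profile as well as the PMF is configurable and defaults to off
for both, since sampling artifacts differ between the two estimates.
Missing or NaN samples are rejected outright rather than imputed —
imputation inside an exponential integral biases the result in an
uncontrolled direction.

Profiles are point samples on an arbitrary strictly increasing grid;
units are declared by the caller (kJ/mol, nm, nm²/ps internally) and
never sniffed from file headers.

## Partitioning

log K_ow = (ΔG_solv,water − ΔG_solv,octanol)/(RT ln 10). The water→skin
coefficient is the spatial Boltzmann average
K = (1/|region|)∫ exp(−β ΔG_rel,water) dz over a configurable z-region,
defaulting to the full bilayer — the conventional reading for membrane
partitioning when the experimental reference is a bulk partition
coefficient. For a region of constant ΔG = c this reduces exactly to
log K = −βc/ln 10, the identity the tests pin. The empirical
log K_w–lip ∝ log K_ow line is fitted by ordinary least squares (optionally
with a fixed intercept); RMSE is computed on log₁₀ values.

## Enhancer insertion

The expected number of enhancer molecules in the bilayer is
N = C·exp(−β ΔG_transfer), with C the number of enhancer molecules in a
formulation volume equal to the simulated system. The bilayer is divided
into 20 equal z-slices and the calculation is done per slice, with
C apportioned uniformly (C/20 per slice, the volume-uniform choice). The
representative Boltzmann factor of a slice is the spatial average of
exp(−βΔG) within it rather than a midpoint value — consistent with the
partition-function character of the formula and stable on coarse grids.
Counts are rounded to the nearest integer before capping, matching the
integer insertion counts the method is used with (16, 18, 24, ...).

Concentration handling: mg/L, g/L and %w/v are converted to molecules/nm³
via c/M·N_A·10⁻²⁴. For ethanol-containing vehicles a configurable
fraction of the ethanol (default 50%) is assumed to evaporate before
partitioning; the removed ethanol mass also removes solution volume
(liquid ethanol density 0.789 g/cm³), so the surviving components are
renormalized to the reduced volume.

The headgroup cap: insertion counts scale exponentially with the PMF
minimum, which can produce unphysical totals. Slices whose centers fall
in the headgroup band are therefore capped so that the post-insertion
headgroup mass (resident water + everything inserted) stays at or below
2.5× the resident water mass — the calibration point being that a pure
water vehicle inserts 100 waters into a system holding 90, a ratio of
≈ 2.1. Capped slices are scaled proportionally with floor rounding
(making the cap idempotent); chain- and tail-region slices are never
capped, as no comparable physical reference exists for them (an optional
tail cap is exposed but off by default). When planned counts
under-predict observed enhancement, the plan is escalated stepwise
(+50% or integer multiples) rather than re-derived; iterative
re-estimation with an updated PMF is supported by simply re-running the
slice calculation.

Placement draws uniform lateral (x, y) positions per molecule at the
slice center z, deterministically per seed, and records the downstream
restraint/equilibration schedule (1000 kJ mol⁻¹ nm⁻² center-of-mass
z-restraint, 5 ns interaction growth, 300 ns equilibration) as metadata
only — running dynamics is out of scope.

## Ionization and flux design

Only the neutral species is assumed to permeate. For a weak acid the
shift is −log₁₀(1 + 10^(pH−pKa)): −0.301 at pH = pKa, vanishing for
pH ≪ pKa, asymptotically −1 log unit per pH unit. The base branch mirrors
the exponent. The pH is taken as an explicit input (the formulation pH in
the worked examples).

The flux-design classifier reads the *formulation-referenced* PMF
minimum: below zero means the permeant prefers the barrier to the
vehicle, so solubility (hence C_v, hence J = C_v·K_P) can be raised with
inert excipients by up to exp(−β·min) before the minimum reaches zero —
e.g. 8.4× for −5.4 kJ/mol and 168× for −13 kJ/mol at 305.15 K. Above
zero, added solubility only deepens the relative barrier and enhancers
are the correct lever. The verdict carries a standing caveat: the bound
conflicts with the classical result that maximum flux from saturated
inert vehicles is solubility-independent, and is a hypothesis to test,
not established theory.

## Synthetic data

Gaussian mixtures generate the test profiles because they have
closed-form extrema and smooth integrands; real profiles are MD outputs
with no parametric form. The reference topography follows the ceramide
bilayer: main barrier in the sphingoid-chain region (4–5 nm), global
minimum at the headgroup band (~3.2 nm) for hydrophilic permeants (inside
the fatty-acid chain region for lipophilic ones), a secondary barrier
near 2.1 nm, on a [0, 5.21] nm domain sampled at 0.01 nm (cell-centered,
matching binned free-energy output grids). The synthetic friction profile
puts 1/g between ~2 × 10⁻⁶ and 5 × 10⁻⁵ nm²/ps — the dense-lipid range —
which yields reference log K_P ≈ −3 for the hydrophilic class, the
realistic order for polar permeants through intact skin. Replicate
ensembles add i.i.d. Gaussian noise per grid point with seeded
determinism.

What the generator does *not* emulate: correlated sampling noise along z,
friction-estimator error structure, asymmetry between leaflets beyond the
built-in asymmetric topography, and any lipid-specific chemistry.
Passing tests therefore demonstrate the correctness of the downstream
arithmetic and its invariants, not the fidelity of any particular MD
force field or sampling protocol.

## Problem sizes

Test and acceptance runs use 521-point profiles (the default grid),
20–25 randomized oracle specs, 100 profile pairs for monotonicity and
replicate ensembles up to n = 1000; the whole suite completes in a few
seconds on one core.

## Known limitations

- Lateral heterogeneity, corneocytes and tortuosity are absent from the
  model by construction; K_P is a lipid-pathway quantity.
- The Boltzmann-average region for skin partitioning and the
  volume-fraction convention are config choices; published partition data
  may use either convention.
- Charged-species permeation is set to zero rather than modelled.
- The escalation workflow is manual by design (factor supplied by the
  user); no convergence loop is attempted.
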