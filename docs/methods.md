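# Methods

## Scope and model overview

The package automates a three-factor, three-level screening of tibial
component implantation angles — coronal varus/valgus (A), posterior slope
of the tibial cut (B), axial external rotation (C) — against the peak
contact pressure on the polyethylene liner under a static 1150 N axial
load at 0° flexion (about twice body weight). The screening uses the
tabulated Taguchi L9(3⁴) orthogonal array, range analysis of the
responses, and a verification evaluation of the predicted optimum.
Responses come from one of three sources: an external response table (the
packaged nine-run reference study, consumed as data), the built-in
elastic-foundation contact surrogate, or an analytic planted-optimum bowl.

## Orthogonal design

Only the tabulated L9(3⁴) (and full factorials) are constructed; general
orthogonal-array synthesis is out of scope for a three-factor screening.
The three factors occupy the first three array columns; the fourth is the
unassigned error column and is dropped on instantiation. Level ordering
follows the study convention exactly, including the non-monotone varus
sequence (0, 3, −3); combination labels use 1-based level indices
(`A1B2C2`). Run order is the canonical row order — the evaluations are
deterministic simulations, so no run-order randomization is applied.
Validation checks column balance (each level 3× per column) and pairwise
orthogonality (each ordered level pair exactly once per column pair) and
reports violations rather than raising.

## Range analysis

Level means K\[j]\[i], ranges R\[j] = max−min of the level means, ranking
by descending range, and the per-factor extremizing level are computed at
full floating precision; two-decimal rounding is display-only. The
objective direction is explicit (default `minimize` — lower peak pressure
means less polyethylene wear). Tie-breaks are deterministic: equal ranges
keep factor declaration order; equal level means resolve to the lowest
level index. No ANOVA, signal-to-noise ratios, or interaction columns are
computed: the method is pure range analysis. For a balanced design the
mean of each factor's level means equals the grand mean, which the tests
assert to 1e-9 relative.

## Elastic-foundation contact surrogate

The liner (E = 685 MPa, ν = 0.4) is far more compliant than the metal
components (E ≥ 117 GPa), so the femoral component is treated as rigid and
the liner as a bonded elastic layer of thickness t = 9 mm: local pressure
p = k·δ with the confined-layer stiffness

    k = E(1−ν) / ((1+ν)(1−2ν)·t) = 163.1 MPa/mm,

δ being the local femur–liner penetration (clamped at zero). This
bed-of-springs model is the standard desk-scale approximation for
conforming implant contact; its pressures are qualitatively, not
numerically, comparable to a continuum finite-element solve, and the
reference study's FE pressure magnitudes are deliberately not reproduction
targets.

**Geometry.** Each compartment is a spherical condyle (R = 30 mm) in a
spherical dish (R = 45 mm, articular aperture 15 mm) centred at ±24 mm
medial–lateral; these dimensions are illustrative of a posterior-stabilized
implant, not vendor geometry, and are config-overridable. A flat dish
(infinite radius) is supported for the closed-form verification case.
Frame: right knee, X medial–lateral (medial +), Y anterior–posterior
(anterior +), Z proximal–distal (the load axis).

**Alignment.** The liner is rotated rigidly about the tray centre,
extrinsically, in the order: external rotation about Z, effective
posterior slope about X, varus–valgus about Y. Positive varus drops the
medial side. The effective slope is the cut slope plus the component's
inherent 3° slope (so the study's "1° posterior slope" articulates at 4°).
All angles are bounded at |angle| < 15°.

**Load path and degrees of freedom.** The axial force acts vertically
through the femoral transepicondylar midpoint (default 25 mm above the
joint line). That point is a material point of the femur: when the femur
tilts into varus the load line shifts medially, generating the adduction
moment that overloads the medial compartment — the mechanism by which the
surrogate reproduces the varus → medial-loading behaviour of a varus knee.
The femoral DOFs are vertical settlement plus the varus–valgus tilt; the
flexion–extension rotation is held fixed (the reference boundary
conditions constrain femoral flexion/extension) and its constraint
reaction moment is reported in the equilibrium state. A free
flexion–extension tilt can be requested, but over spherical dishes it
would let the condyles roll to the dish bottoms and null the slope factor.
In-plane translations are neglected for the conforming dishes, and the
axial spin is a null DOF under frictionless vertical contact. Friction
(μ = 0.04) is recorded as metadata only.

**Ligaments.** The collateral ligaments are point-to-point, tension-only
vertical springs at ±40 mm lever arms, with incompressible Neo-Hookean
uniaxial response: Cauchy stress σ = 2C₁(λ² − λ⁻¹), force σ·A₀/λ, zero
below the reference length. C₁ = 6.43 MPa (medial) and 6.06 MPa (lateral);
the tangent stiffness dσ/dλ at λ = 1 is 6C₁. Rest lengths (90/60 mm),
cross-sections (25/15 mm²) and attachment sites are not published implant
or subject data; they are anatomically plausible placeholders, flagged as
such, and config-overridable. The tension force σ·A₀/λ is strictly
increasing but concave in λ (the 1/λ current-area factor); the convexity
property belongs to the stress σ(λ).

**Equilibrium solve.** The settlement is first bracketed and solved at
zero tilt (Brent's method on the monotone force residual), then a damped
Newton iteration (forward-difference Jacobian; damping factor 0.5 while
the residual norm grows; hard cap 100 iterations) drives the scaled
residuals — vertical force relative to the applied load, free-tilt moments
relative to load × 24 mm — below 0.1%. Vertical femoral equilibrium is
contact = applied load + ligament pull, so the pressure integral equals
1150 N exactly when the ligaments are slack (zero and small misalignment)
and exceeds it by the ligament tension when a collateral engages; the load
balance is conserved to well under 0.5% in either case. Failure modes:
non-convergence raises with the last residual; an alignment that admits no
contact raises "load cannot be equilibrated".

**Verification against a closed form.** For a single sphere (radius R) on
a flat foundation with tilts frozen and no ligaments, the parabolic
approximation gives F = π·k·R·δ² and peak p = k·δ for apex penetration δ.
At 0.25 mm grid spacing the solver matches the force within 0.34% (the
residual is dominated by the sphere-vs-parabola profile difference,
~a²/6R² ≈ 0.3% at contact radius a ≈ 4 mm) and the error shrinks under
grid refinement.

**Numerical choices.** Grid: symmetric cell-centred axes at 0.5 mm default
spacing (0.25 mm for the oracle case), covering every aperture with a 3 mm
margin; a grid coarser than 8 cells per aperture diameter is rejected.
Peak-pressure ties resolve to the medial compartment, then to the lowest
grid index. Pressure-map export prints 17 significant digits so a
write/read round trip is bit-identical.

## Planted-optimum response

A convex quadratic bowl base + Σ w_f(angle_f − opt_f)² stands in for the
response so the pipeline's optimum recovery can be measured independently
of the solver. Defaults, chosen once as the study conditions: optimum at
(0°, 1°, 4°) — on the level grid, so a noiseless L9 screening recovers it
exactly; curvature weights (0.9, 0.7, 0.6) MPa/deg², ordered
varus > slope > rotation so the L9 ranges rank in that order (the varus
levels span ±3° against ±1° for the others, which amplifies its range to
9·w_A); base 16.4 MPa, matching the scale of the verified optimum run.
Gaussian noise requires an explicit seed; under 2%-of-base noise the
recovery rate over 50 seeded replicates sits near 98% — a property of this
configured bowl, not a general claim.

## What the surrogate and generator do and do not show

Passing tests demonstrate the internal mechanics (load conservation,
symmetry, closed-form agreement, qualitative varus → medial loading) and
the correctness of the design/analysis machinery on exact and planted
data. They do not validate the surrogate against continuum FE magnitudes:
with spherical, highly conforming dishes the surrogate's peak pressure is
less sensitive to the varus angle than the reference FE study (where varus
ranks first), because conforming sphere-in-sphere contact largely
re-centres under tilt; slope and rotation act through contact-patch offset
against the fixed flexion–extension constraint. Real implant surfaces are
toroidal and less conforming, real ligament geometry is subject-specific,
and real loading is dynamic — none of which the surrogate claims to
capture.

## Pipeline and reproducibility

The YAML config selects exactly one response source and can override
factors, geometry, materials, ligaments, and load; unknown keys are
rejected with field paths; omitted blocks take the documented defaults. In
external-response mode the verification value (the optimum run's measured
response) must be supplied, since no evaluator exists to compute it. All
outputs (design table, response table, text and JSON reports, resolved
config) are deterministic: identical config and seed give byte-identical
files; timestamps appear only on the logging stream. The acceptance script
re-runs the whole chain — combinatorics, fixture analysis, verification
arithmetic, 50-replicate recovery at the given seed, and the surrogate
checks — in a few seconds.
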