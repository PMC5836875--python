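# Methods

## The diagnostic model

The package estimates the fraction of diseased ("cancerous") tissue in a
sample from a single creep or stress-relaxation test, assuming the
viscoelastic laws of the two constituent tissues are known.  Each phase is a
linear viscoelastic solid with a Prony-series relaxation modulus

    E(t) = E0 · (1 − Σ_i D_i · (1 − e^(−t/τ_i))),

where `E0` (Pa) is the instantaneous modulus, `D_i ∈ (0,1)` the stiffness
loss of term *i*, `τ_i` (s) its relaxation time, and `Σ D_i < 1` so the
long-term modulus `E0(1 − Σ D_i)` stays positive.  A widely circulated
typeset of this law places the leading 1 inside the sum, which would
multiply `E0` by the number of terms; the form above is the standard one and
coincides with the other reading for a single term, the only case the
homogeneous fit ever uses.

### The rule of mixtures

The sample is idealized as a unit-length biphasic rod: a cancerous segment
of length `l_c` in series with a healthy segment of length `1 − l_c`, loaded
by a constant axial force `F` on cross-section `A`.  Using the quasi-elastic
convention (time-domain compliance `1/E(t)` per phase), the free-end creep
displacement is

    u_het(t) = (F/A) · [ l_c / E_c(t) + (1 − l_c) / E_h(t) ].

An equivalent homogeneous rod with a single-term Prony law
`(E_hm, D_hm, τ_hm)` has `u_hom(t) = F / (A · E_hm(t))`.  Strain-energy
equivalence between the two systems under constant stress reduces to
matching displacements, so the apparent properties solve

    min ∫₀^{t_exp} (u_het − u_hom)² dt   s.t.  E_hm, τ_hm > 0,  0 < D_hm < 1,

with `t_exp` the hold duration of the examination.  Solving this for a grid
of fractions (default 0 to 1 in steps of 0.01) tabulates the rule of
mixtures `l_c ↦ (E_hm, D_hm, τ_hm)`.  Only `τ_hm` is used diagnostically:
a measured trace is fitted with a single-term Prony law and its apparent τ
is inverted through the tabulated `l_c ↦ τ_hm` map.

The upper bound `D_hm < 1` is imposed in addition to the bare positivity
constraints because a homogeneous material with `D ≥ 1` has a non-positive
long-term modulus.  The rule is always built from the creep form, even when
the measured trace is a relaxation test; on the exact 1D model the two
conventions give apparent τ values agreeing to better than 0.5% for the
configurations exercised here (the discrepancy is reported by the tests, not
assumed zero).

### Numerical treatment of the minimization

The integral is evaluated by the trapezoidal rule on `0..t_exp` with step
`dt = 0.05 s`.  The unknowns are transformed to
`(log E_hm, logit D_hm, log τ_hm)` so every constraint holds by
construction, and the problem is solved as a weighted nonlinear
least-squares (trust-region reflective) whose cost equals the trapezoid
integral exactly — the residuals are `√w_k · (u_het(t_k) − u_hom(t_k))` with
`w_k` the trapezoid weights.  Five deterministic multi-starts guard against
local minima: the two constituents, the fraction-weighted and
reverse-weighted blends of their transformed parameters, and the
log-midpoint with `D = 1/2`.  Rule construction additionally warm-starts
each fraction from the previous solution.  At the grid endpoints the
heterogeneous curve is exactly representable, so the fit recovers the
constituent parameters to optimizer tolerance (≤ 1e−6 relative in the
tests).  Halving `dt` moves fitted τ values by well under 0.5%.

### Trace characterization

Measured or simulated traces are fitted over the hold window only, with the
clock re-zeroed at hold start and the signal normalized by its value there,
so the geometry- and load-dependent scale drops out and only `(D, τ)` are
identified.  The fitted model carries a free amplitude `s ≈ 1`: without it,
noise on the single normalizing sample would bias every residual
coherently, and with it the median τ recovery error under 1% multiplicative
noise on 200-point traces is ~1.3%.  A trace whose relative decay is below
1e−4 is flagged `tau_unidentifiable` (τ cannot be estimated from a flat
signal) rather than raising; a trend that rises beyond 5% of the total decay
gets a `non_monotone` warning.

Inversion uses piecewise-linear interpolation on the monotone envelope of
the tabulated τ column; τ values outside the rule's range clamp to fraction
0 or 1 with an explicit flag, and a rule whose τ column is non-monotone by
more than 1% of its range raises an error listing all candidate fractions
instead of silently picking one.  Rules are cached by a content hash of
(materials, protocol, grid, dt), so repeated diagnoses against the same
tissue pair cost one table lookup.

## The virtual-palpation simulator

The simulator provides seeded relaxation experiments with known ground
truth.  A rectangular sample is meshed with bilinear quadrilateral elements
on a regular grid (default 40×40, element size 0.5 mm, i.e. a 2 cm sample);
each element carries one phase's material.  Random microstructures assign
exactly `round(fraction · nx · ny)` cancerous elements uniformly without
replacement from a seeded generator, so the realized fraction differs from
the target by at most one element and every study is reproducible from its
seed list.

Kinematics are small-strain plane stress (unit thickness).  Viscoelasticity
enters as a single scalar relaxation function per element applied to the
whole elastic stiffness — equivalently, a constant Poisson ratio (default
ν = 0.45 for both phases, configurable).  This convention makes the 1D
Prony law the *exact* solution for a homogeneous sample under the solver's
frictionless boundary conditions, giving a closed-form oracle: the
homogeneous step-relaxation trace reproduces `E(t)/E0` to machine precision.
Time integration uses the exact exponential recurrence for the internal
variables `h_i` (exact for strain varying linearly within a step); because
the effective stiffness factor is constant at fixed step size, the sparse
LU factorization is computed once per run and reused for every step.  An
ideal step (`ramp_time = 0`) is handled by an instantaneous elastic solve
with fully loaded internal variables.

Boundary conditions: a rigid, flat, frictionless platen covers the full
indented edge (normal displacement prescribed, tangential free); the
opposite edge is a frictionless support, with one corner pinned tangentially
to remove the rigid-body mode; the lateral edges are traction-free.
"Lateral" indentation is realized by transposing the label grid, which is
exact for an isotropic constitutive model.  The default protocol ramps the
platen linearly for 1 s and holds for `t_exp` (default 5 s), sampling the
total platen reaction at 50 ms.

### What the simulator does and does not emulate

It reproduces the statistical scatter of random biphasic microstructures,
the ramp-and-hold loading of instrumented palpation, and exact linear
viscoelastic relaxation.  It does **not** model finite strains, contact with
partial or curved indenters, friction, anisotropy, poroelastic fluid flow,
or real tissue geometry (histology- or image-derived domains).  Passing the
end-to-end tests therefore demonstrates the correctness and internal
consistency of the inversion pipeline on its own model class, not clinical
accuracy on real tissue.

### Known model-form bias of the series rule on 2D microstructures

The rule of mixtures is exactly the series (Reuss, compliance-averaging)
bound.  A genuinely two-dimensional random microstructure is stiffer and
slower than that bound: its apparent τ lies strictly between the FE
series-laminate and parallel-laminate values (verified by the tests).
Because the rule is shallow at low fractions whenever `t_exp ≪ τ_c`, even a
~10% upward τ bias maps to tens of percentage points of overestimated
fraction.  On the default 17/34 kPa, τ = 1 s/10 s configuration the maximum
end-to-end fraction error over 40 seeded runs is ≈ 34 percentage points,
with the estimate always biased high; the acceptance script recomputes this
number from scratch.  Sharper fraction recovery on dispersed 2D
microstructures would require a 2D-aware effective-medium rule, which is
outside this package's scope.

A related, smaller effect appears in the laminate oracle: at ν = 0.45 a
bonded square laminate is ~0.5% stiffer than the series-compliance closed
form because the layers' mismatched lateral contractions are constrained
near the interface.  The oracle tests therefore exercise the closed form
where its assumptions hold — at ν = 0 (agreement to machine precision) and
on a slender 4×40 stack at the default ν (0.06% deviation).

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `E0` healthy / cancerous | 17 / 34 kPa | instantaneous moduli (stiffness ratio 1:2; 1:5 variant uses 85 kPa) |
| `D` both phases | 0.5 | stiffness-loss fraction; not reported in the source literature for these tissues, so a mid-range value is fixed and user-overridable |
| `τ` healthy / cancerous | 1 s / 10 s | relaxation times (1:100 variant uses 100 s) |
| `t_exp` | 5 s | hold duration; a clinical tuning parameter |
| ramp time | 1 s | platen loading ramp |
| `dt` | 0.05 s | sampling and quadrature step |
| fraction grid | 0:0.01:1 | rule tabulation grid |
| mesh | 40×40, 0.5 mm elements | simulator resolution (≈3.4k unknowns, direct sparse solve) |
| ν | 0.45 | common Poisson ratio, quasi-incompressible tissue |
| platen displacement | 5% of sample height | keeps the small-strain assumption honest |

## Problem sizes used by the shipped studies

The test-suite and acceptance studies run at desk scale: rules of 101
fractions on 101–1001-point time grids, FE meshes of 100–1600 elements with
120–240 time steps, 40-run end-to-end suites, and a 100-seed Monte-Carlo
noise study.  These sizes were chosen so every study is exactly re-runnable
from its seeds in seconds to a few minutes on a single core.

## Degenerate inputs and tie-breaks

Identical constituents produce a rule with a constant τ column; inversion
then returns the leftmost grid point of the (flat) envelope.  Fraction-0 or
fraction-1 microstructures are valid and exercise the null and saturated
diagnosis paths.  Optimizer non-convergence is never silent: fits carry a
`converged` flag, rules list their failed fractions, and the parametric
suite records per-cell failures in a `status` column while continuing.
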