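# Methods

This note records the models, numerical choices and known limitations behind
`auxqmmm`.  Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Units and conventions

Hartree atomic units internally (bohr, hartree, e, electron mass); file
formats and MM parameter files use Å, kcal/mol, degrees, amu and fs and are
converted on read (1 Å = 1.8897261254578281 bohr).  Atom indices are
0-based in the API and 1-based in user-facing reports.  All systems are
non-periodic clusters.

## Basis functions and integrals

Orbitals are contracted Cartesian Gaussians up to d; auxiliary functions
are primitive Hermite Gaussians c̄(r) = norm · (∂/∂C)^(t,u,v) exp(−ζ|r−C|²)
with total Hermite order ≤ 2 and norm = (2ζ/π)^¾ (2ζ)^(|t,u,v|/2) (a pure
conditioning scale; `normalized=False` gives the bare derivative Gaussian).
This convention is used consistently by the two- and three-center repulsion
integrals, the density fit and the quadrature code.

Integrals are evaluated in a McMurchie–Davidson scheme: Hermite expansion
coefficients by recursion, Coulomb kernels by the Boys-function derivative
tensor R_{tuv}.  The Boys function uses a Taylor series below x = 1 and the
regularized lower incomplete gamma function above, with downward recursion
in the order; absolute accuracy is ~1e-14 for n ≤ 32, x ≤ 200 (checked
against 30-digit quadrature).  The contract for every integral class is
agreement with independent numerical oracles (range-separated spherical/box
quadratures, closed forms, symbolic differentiation), not a particular
recurrence.

Two built-in basis sets ship as Gaussian94-style text (`data/*.gbs`): a
minimal STO-3G-like set and a valence-double-zeta-plus-polarization set
constructed here by splitting the minimal valence shells and adding one
polarization shell (p on H/He, d on C/N/O).  Auxiliary sets are generated
even-tempered: per element, a geometric exponent ladder (ratio 3) covering
the density exponent range [2ζ_min, 2ζ_max] of the orbital set, s-type by
default with an spd option.  These sets are this package's own; their only
claims are the variational-bound and cross-check properties the tests
verify.

## Far-field machinery

*Extents.*  A shell's extent at threshold τ is the radius beyond which its
maximal radial amplitude Σ|d_k| R^l exp(−ζ_k R²) stays below τ (bisection).
An auxiliary's potential extent is the radius beyond which its electrostatic
potential differs from the point-multipole limit by less than τ; the erfc
residual bound carries a factor (1 + 2ζR²)^(|index|/2) because every Hermite
derivative multiplies the exponential tail by ~2ζR.  Boundary ties classify
as near (conservative, deterministic).

*Expansion center.*  The multipolar expansions are Taylor series about an
orbital center; the code always expands about the **tighter** shell's center,
where the orbital product is localized.  (Expanding about a diffuse H center
when the product sits on a tight O core costs ~1e-3 in the embedding matrix;
the tighter-center rule restores ~1e-10 agreement.)

*Embedding.*  Point charges are classified per shell (near iff inside the
extent sphere of either shell of the pair, resolved through precomputed
per-atom auxiliary fields); far-field charge sums Σ_D Q_D T(m) are
accumulated once per (QM atom, m) and corrected per pair for the few sites
near only the partner atom.  The factorized and naive accumulations agree to
1e-12 by construction (regression-tested).

*Near/far 3-center ERIs.*  The SCF provider classifies contracted
(shell-pair, auxiliary) triplets with the Gaussian-interaction radius
R = sqrt(ln(pref/τ)/μ_eff) + |A−B| about the tighter center, with
μ_eff = p·ζ_c/(p+ζ_c) combining the minimal product exponent with the
auxiliary exponent — deliberately conservative; the three SCF schemes agree
to ~1e-10 hartree under it.  The near-field **store size** (what the mixed
scheme would hold in memory) is counted at the level integrals are actually
produced, primitive Gaussian products: each screened primitive pair owns a
product center and exponent, and an auxiliary is near within
sqrt(ln(0.1·pref/τ)/μ_eff) of that center, where pref is the magnitude
prefactor of the corresponding Coulomb integral and the 0.1 calibration
makes the expansion error just outside the radius of order τ (worst corner
cases, tight offset products, reach ~1e-7; typical ≤1e-9).  Under this count
the C8→C16→C32 alkane ratios are 2.28 and 2.12 — the counts are affine in
chain length, with end effects supplying the deviation from exactly 2.

## SCF

Restricted closed-shell only.  Convergence by DIIS on the commutator
K·P·S − S·P·K with optional damping; the core-Hamiltonian guess; RMS
density-change tolerance 1e-7 by default.  The fit solves G x = J through an
eigen-pseudoinverse with a relative eigenvalue cutoff of 1e-10.  The
exchange-correlation term uses Dirac exchange with VWN (form V)
correlation on the fitted density; negative fitted density at grid points is
clamped to zero and counted in the cycle log.  The Kohn–Sham matrix is
H + Σ_c̄ (x_c̄ + z_c̄)⟨ab‖c̄⟩ with z = G⁻¹⟨c̄|v_xc⟩ — the chain-rule term from
the density dependence of the fit — and is validated as the
finite-difference derivative of the energy functional (≤1e-6 per element;
measured ~2e-9).

*Grid.*  Becke fuzzy-Voronoi partition (three smoothing iterations, no size
adjustment) over per-atom grids: 40 Gauss-Chebyshev radial points mapped by
r = r_m(1+x)/(1−x), and a Gauss-Legendre(16) × uniform-φ(32) spherical
product rule.  The named contract is that a normalized s-Gaussian integrates
to 1 within 1e-6 on any atom; a product rule of this degree meets it with
margin and avoids hard-coded angular weight tables.

*Reference implementation.*  `reference.py` is an independent dense
implementation of the same fitted-density model for s-orbital systems:
closed-form s integrals (error-function Coulomb kernels), its own
functional formulas and a plain damped fixed-point loop.  He and H2 agree
with the main engine to ≤1e-10 hartree (measured 4e-16).  It shares only
the quadrature grid object, which is part of the model definition being
compared.

*Density-fitted exact exchange* is available as an energy-only option in
the full-domain (non-local) limit, X_ab = Σ_i Σ_c̄d̄ ⟨ai‖c̄⟩G⁻¹⟨d̄‖ib⟩; with a
product-spanning auxiliary set it reproduces brute-force four-center
exchange to 1e-8.  Locality domains are an exposed hook without defaults.

## MM force field

Class-I functional forms with the ½k convention for bonds, angles and
Urey-Bradley terms and V_n(1 + cos(nφ − δ)) dihedrals; 12-6 van der Waals
written as ε[(R_min/r)¹² − 2(R_min/r)⁶] with Lorentz/geometric combination;
bare Coulomb; no cutoff (full double loops).  Exclusions: 1-2 and 1-3
excluded, 1-4 at full strength (configurable); the QM–MM Lennard-Jones
coupling applies the same exclusions across the boundary.  All analytic
gradients are validated against central finite differences (~1e-10).
Parameter files (`data/standard.ff`) are a documented plain-text dialect in
kcal/mol, Å and degrees covering the shipped fixtures: flexible SPC-charge
water (stiff bonds stand in for rigid constraints; the hydrogens carry the
standard small Lennard-Jones well, without which a bare charged H collapses
onto a neighboring O), OPLS-like united alkane types, and monatomic ions.

Drude oscillators are massless charges on harmonic springs attached to
heavy atoms; the relaxation solver places each Drude at q′E/k in the field
of everything else and iterates to a force residual ≤1e-8 (replacing
extended-Lagrangian propagation).  The closed forms d = q′E/k and
α = q′²/k are exact to 1e-10.  The pair-enumeration convention: every
particle pair interacts by Coulomb unless excluded, exclusions inherited
through the anchor (a Drude never sees its own anchor).

## Coupling layer

Link atoms use α = r_eq(QBA–H)/r_eq(QBA–MBA) from a small equilibrium-length
table (the printed ratio definition is dimensionally inconsistent as a
vector ratio; the scalar form is what the position definition implies).
QM nuclear gradients are central finite differences of the embedded SCF
energy with link atoms re-placed at each displacement; embedding-site
gradients are analytic Hellmann-Feynman sums; link forces are projected by
(1−α)/α onto the hosts.  The MM boundary atom's point charge is excluded
from the embedding by default (closest-charge overpolarization guard).
In the MM-region energy, bonded terms with at least one MM atom are kept
and nonbonded terms run over MM–MM pairs only.

FIRES applies the half-harmonic penalty only to outer molecules inside
R_in = max inner-tag distance (the literal sum over all outer molecules
would penalize molecules far outside the sphere).  The reaction force can
land entirely on the boundary tag atom (the literal recipe, default) or be
spread uniformly over the opposing tag set (`reaction="distributed"`); both
give zero net restraint force, but in an all-MM droplet — where the inner
and outer solvent molecules are physically identical and constantly exchange
pressure across the boundary — the concentrated reaction catapults single
molecules and destroys the separation, so droplet dynamics use the
distributed mode together with the mirrored inner-side restraint
(`symmetric=True`), a weak spherical harmonic container around the droplet
and a fixed reference atom.  With k = 200 kcal/mol/Å² this holds the inner
set's identity over 1,000 production steps with maximum transient
penetration ≤ 0.26 Å across seeds.

## Sampling

Velocity Verlet; Langevin thermostat in the BAOAB splitting (friction in
fs⁻¹, deterministic under a seed).  The FEP estimator is per-window
exponential averaging with standard errors from three-block averaging,
forward and backward directions reported separately; the default protocol
is 11 λ-windows.  The replica-exchange sweep alternates odd↔even and
even↔odd nearest-neighbor pairs and accepts with
min{1, exp(−β[U_i(q_j)+U_j(q_i)−U_i(q_i)−U_j(q_j)])}; the β factor is
included explicitly (an exponent over energies is dimensionless only with
it), and acceptance swaps the pair's configurations.

The harmonic-alchemy fixture (k: 1 → 4 at kT = 1) samples each window from
its exact Gaussian distribution, isolating estimator statistics from
integrator error; it recovers dF = ½ln 4 within three standard errors at
10⁵ samples per window, with forward/backward hysteresis consistent with
zero.

## What the fixtures do and do not show

The generated droplets, alkane chains and harmonic toys exercise every code
path at sizes where exact cross-checks are affordable: water droplets are
rejection-packed at liquid-like density (29.9 Å³/molecule) with
liquid-like contact distances, alkanes are ideal tetrahedral chains, and
ions carry generic monatomic parameters.  Passing tests therefore
demonstrate the *machinery* — integral accuracy, scheme equivalence,
variational bounds, force consistency, estimator correctness — not the
quality of any force field or basis for real chemistry: the shipped
parameter and basis sets are deliberately small, droplet structure is not
equilibrated liquid water, and no periodic boundary conditions, Ewald
summation, SHAKE constraints, open-shell SCF, GGA/hybrid functionals in the
SCF, or analytic QM nuclear gradients are provided.

## Problem sizes

The validation pipelines run at fixed desk-scale sizes chosen so each
quantity has an exact counterpart: 500 randomized integral cases per
far-field class; water/DZVP-like in 2,000 charges for the embedding matrix;
water/minimal in 500 charges for the scheme equivalence; C8–C32 alkanes for
the near-field scaling; a 21-water ion droplet for 1,000 MD steps; 10⁵
samples per FEP window and 10⁵ exchange attempts.
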