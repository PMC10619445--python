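# Methods

This note records the model definitions, numerical choices and known
limitations of the package, in the order a reader would meet them.

## Monomer wavefunctions

The models operate on *frozen* closed-shell monomer wavefunctions.  The
in-process provider is a restricted Hartree–Fock engine (DIIS-accelerated,
convergence 1e−10 hartree / 1e−8 on |FDS−SDF|) over McMurchie–Davidson
Gaussian integrals supporting segmented or general contractions and pure
or Cartesian shells up to l = 4.  Orbitals from any other method label
(LDA, BLYP, B3LYP, ωB97X, ωB97M-V, …) enter through the file-based
provider: a pure-spherical-dialect Molden reader.  All five energy terms
are evaluated with Hartree–Fock energy *expressions* applied to whatever
occupied orbitals are supplied, so the term definitions are independent of
the orbital source.  Open-shell species are rejected; spherically averaged
open-shell *atoms* (for free-atom references) are solved with fractional
occupation of the degenerate frontier manifold, and one-electron species
by exact diagonalization of the core Hamiltonian.

No effective core potentials are implemented: the supported element range
(H–Ar) is all-electron.

## Basis set

The package ships one basis, labelled `svp-like`, generated by
`scripts/make_basis.py`: per element an even-tempered primitive set
(α₀·βⁱ) whose two (four, with p) parameters are optimized by minimizing
the spherically averaged atomic HF energy; general contractions are taken
from the occupied atomic orbitals; the two most diffuse primitives of each
angular block stay uncontracted (split valence); one fixed polarization
shell is appended per element, and chlorine additionally carries one extra
diffuse s and p function for anion work.  Quality benchmarks (atomic
energies): Ne −128.510 vs the −128.547 HF limit, Ar −526.733 vs −526.817 —
split-valence-polarization territory.  The basis is a *synthetic*
construction of this package (its generation script is shipped and
re-runnable); it is not a literature basis set, and `def2-svp` is accepted
as an alias purely for interface compatibility.

## The five components

With monomer occupied coefficient blocks stacked into a dimer "superposed"
wavefunction (no orthonormalization):

* `E_coul`: Tr(P_A·J[P_B]) + Tr(P_A·V_B^nuc) + Tr(P_B·V_A^nuc) + Z_A Z_B
  cross terms — the exact classical electrostatic interaction of the two
  frozen charge distributions.
* `E_exch`: −½ Tr(P_A·K[P_B]), the inter-monomer HF exchange of the
  *pre-orthogonalization* densities.  (Whether exchange should use pre- or
  post-orthogonalization densities is a genuinely open convention; the
  pre-orthogonalization choice is normative here and the alternative can be
  probed by editing one line in `exchange_repulsion`.)
* `E_rep`: the occupied MOs of the superposed dimer are symmetrically
  (Löwdin) orthonormalized in the occupied-block metric, and
  E_rep = E[orthonormalized determinant] − E_A − E_B − E_coul − E_exch.
  By construction E_rep → 0 identically when the inter-monomer overlap
  vanishes; in floating point the cancellation of total energies
  (~hundreds of hartree) leaves a residual of order 1e−11 hartree, which
  is what the corresponding test asserts.
* `E_pol`: −½ Σ_{i∈A} αᵢ|F_B(rᵢ)|² − (A↔B), fields of the partner's full
  frozen charge distribution evaluated **at the nuclear positions** only,
  matching the atom-centred polarizability model.
* `E_disp`: XDM, below.

A model total is a pure linear combination — components are never
recomputed or mixed during scaling.

## XDM dispersion and atom-in-molecule polarizabilities

Becke–Roussel exchange-hole dipoles are obtained per grid point by
bracketed bisection (tolerance 1e−10) of x·e^(−2x/3)/(x−2) = ⅔π^{2/3}ρ^{5/3}/Q
on the monotone branch — (2,∞) for Q > 0, (0,2) for Q < 0 — with
Q = (∇²ρ_σ − 2D_σ)/6, D_σ = τ_σ − ¼|∇ρ_σ|²/ρ_σ (τ without the ½
convention), and hole displacement d = b, b³ = x³e^{−x}/(8πρ_σ).  Densities
below 1e−14 return d = 0.

Hirshfeld stockholder weights use spherically averaged free-atom densities
computed on demand by the package's own atomic solver and cached (radial
tables, log-interpolated with exponential tail extrapolation).  Atomic
moments ⟨M_l²⟩ = Σ_σ ∫ w_i ρ_σ [r_iˡ − (r_i−d_σ)ˡ]², Hirshfeld volumes
V = ∫ w_i ρ r_i³, and effective polarizabilities α = α′·V/V′.  Pair
coefficients use the standard second-order combining rules
(C₆ = αᵢαⱼM₁ᵢM₁ⱼ/(M₁ᵢαⱼ+M₁ⱼαᵢ), etc.); damping uses
R_crit = mean of the three equal-term radii and R_vdW = a₁R_crit + a₂ with
a₁ = 0.65, a₂ = 1.70 Å fixed (never fitted; exposed in `XDMParams` for
research use).

Physical calibration: the model reproduces noble-gas C₆ within ~20%
(He 1.72 vs 1.46 exact, Ne 5.9 vs 6.4, Ar 51 vs 64 with this basis), the
known accuracy envelope of the exchange-hole dipole construction on
modest-basis HF densities.  No external dispersion reference program is
used anywhere; correctness rests on analytic round-trips, symmetry,
homogeneity and grid-refinement tests.

Two dispersion-interaction modes exist and are tagged in every output:
`monomer` (default; cross pairs with monomer coefficients) and `dimer`
(total-minus-monomers with coefficients from the concatenated dimer).

### Free references and the polarizability table

α′ values are a tabulated compilation of neutral-atom static dipole
polarizabilities (editable in `ce1p.constants`).  Two deliberate choices:

1. A *bare monatomic ion* references its own charge state — its free
   density, volume and (for alkali cations, where the neutral valence
   electron is absent altogether: Li⁺ 0.192, Na⁺ 0.998, K⁺ 5.34 bohr³)
   its ion polarizability.  For such species V/V′ = 1 exactly.  Referencing
   Na⁺ to neutral Na (α′ = 162.9 bohr³) would be qualitatively wrong.
2. Atoms *inside* molecules always reference neutral free atoms (the
   standard stockholder choice), regardless of the molecule's net charge.
   Halide anions therefore carry the neutral-element α′ scaled by their
   volume ratio; gas-phase anion polarizabilities are substantially larger,
   and this is a documented model limitation (condensed-phase anion
   polarizabilities are strongly quenched, which this convention
   approximates better than the gas-phase ion value would).

## Integration grids

Atom-centred Becke grids: Gauss–Chebyshev (2nd kind) radial nodes under the
rational map r = R_m(1+x)/(1−x) with R_m from Bragg–Slater radii, 75 radial
points by default; the angular factor is a Gauss–Legendre × uniform-φ
product grid (n_θ = 17, n_φ = 2n_θ → 578 points), exact for spherical
harmonics to degree ≈ 2n_θ; Becke cell functions with three smoothing
iterations and no atomic-size adjustment.  Measured accuracy: ∫ρ for water
reproduces 10 electrons to 3e−7; doubling both grid dimensions moves
Hirshfeld volumes and ⟨M₁²⟩ by <0.5%.  Lebedev tables are deliberately not
used — the product grid needs no tabulated constants and its rotational
variance is below 1e−9 in the moments, which the rigid-motion invariance
test (drift < 1e−7 hartree per component) bounds end-to-end.

## Charge-transfer screen

Löwdin monomer charges of the orthonormalized dimer are compared with the
formal monomer charges; a pair is *flagged* when the larger deviation
strictly exceeds the threshold (default 0.33 e, configurable — the
threshold is an implementation choice, not a literature constant).
Flagged pairs are excluded from fits; energies are never altered.

## Crystals

CIF ingestion (gemmi) canonicalizes symmetry operations (explicit
`_symmetry_equiv_pos_as_xyz` preferred, Hermann–Mauguin fallback, P1 with a
warning otherwise) and rejects partial occupancy outright.  Molecules are
connected components of a covalent-bond graph (distance < 1.25 × sum of
covalent radii) tracked across periodic images; inconsistent image shifts
(infinite connectivity) raise "not a molecular crystal".  Alkali and
alkaline-earth elements are treated as non-bonding during extraction so
that ionic crystals resolve into monatomic ions.  Unique molecules are
grouped by their interatomic-distance fingerprint; every instance stores
the orthogonal Cartesian map (M, t) from its unique reference — improper
operations included, handled for pure shells as (−1)ˡ × the rotation block
of −M — so each symmetry image's wavefunction is a cheap coefficient
transformation, never a new SCF.

Dimer classes are keyed by the sorted multiset of inter-monomer atom
distances at 1e−3 Å resolution; multiplicities count occurrences per unique
central molecule.  Lattice energies are direct sums
E_lat = ½ Σ_classes multiplicity × E_tot with a convergence probe at
cutoff + 5 Å reported in every trace (default cutoff 15 Å,
closest-contact criterion).  X—H bond lengths can be normalized to average
crystallographic values (C–H 1.083, N–H 1.009, O–H 0.983, B–H 1.180 Å —
standard neutron averages, fully configurable).

**Polarization in crystals.**  Pairwise mode sums −½α|F|² per dimer;
crystal-field mode sums the neighbour field *vectors* at each atom of the
central molecule before squaring (per-molecule attribution of the
difference is even across unique molecules; the total is exact).  Direct
summation of E_coul for charged species is conditionally convergent and
triggers a warning; the ionic fixture is used for polarization analysis,
not total lattice energies.

`lattice_polarization` specializes this comparison with a far-field
treatment: neighbours beyond the QM cutoff (12 Å default) are point
charges at their centroids out to 250 Å, plus an analytic 4πn/R continuum
tail for the pairwise |F|² lattice sum (the 1/r⁴ sum converges only as 1/R,
so the tail matters at the percent level; with these defaults the residual
truncation error is ≈0.1%).  On ideal rock-salt NaCl this yields the
package's headline demonstration: the crystal-field polarization vanishes
identically by symmetry while the pairwise sum gives a spurious
stabilization of ≈417 kJ/mol per formula unit (α_eff(Na⁺) ≈ 1.0,
α_eff(Cl⁻) ≈ 14.6 bohr³ under the conventions above; the magnitude is
directly proportional to α_eff(Na⁺)+α_eff(Cl⁻) and therefore tracks the
polarizability table).

## Fitting

`scan_k` evaluates the CE-1p error curve on a k-grid (ties broken toward
smaller k), `fit_two_parameter` solves the linear RMSD minimum in
(k_exch-rep, k_pol) and reports the error surface, `fit_five_parameter`
uses bounded linear least squares (bounds [0,3], k_rep ∈ [0.6,3]; active
bounds reported).  The loss is RMSD; MAD is available behind a flag.
Rows flagged by the charge-transfer screen are excluded with a logged
count; group-stratified statistics are supported via a `group` column.
RMSD ≥ MAD ≥ |MSD| holds by Jensen/triangle inequalities and is enforced
as a property test.

## Synthetic data and what the tests do (and do not) show

All fixtures are generated: point-charge pseudo-monomers with closed-form
fields (electrostatics oracles), a rigid hydrogen-bonded water dimer and
its scaled-separation series, an ideal NaCl lattice, an idealized
urea-like P1 crystal and a synthetic P2₁/c water packing (both labelled
synthetic — they are constructions, not deposited structures).  Fit tests
draw component tables whose references are generated by known scale
factors with optional Gaussian noise (σ = 1 kJ/mol at n = 500 for the
noisy-recovery check), which verifies the estimators, not the physics of
any particular training set.  Passing tests therefore demonstrate: exact
component definitions and limits, rigid-motion/symmetry consistency,
estimator correctness, and the ionic polarization pathology — they do not
certify benchmark-set error statistics, which require external reference
data and wavefunction sources beyond HF.

## Problem sizes and budgets

Default test problem sizes are deliberately small molecules (He, H₂, H₂O,
Na⁺, Cl⁻, water dimer) where every SCF is seconds; the NaCl demonstration
uses a 12 Å quantum-mechanical neighbour shell (680 dimers) chosen because
field penetration beyond that range is below machine noise, with the
remaining lattice handled analytically as described above.

## Known limitations

* HF-only in-process provider; DFT orbitals must come from Molden files.
* All-electron H–Ar (+ tabulated constants for Br, I); no ECPs.
* Gas-phase monomer wavefunctions: crystal-environment pre-polarization is
  absent, a known competing error against pairwise over-polarization.
* No forces/gradients, no periodic electrostatics (Ewald), no three-body
  dispersion, no charge-transfer energetics (the screen only excludes).
* Legacy CE-HF/CE-B3LYP presets are included `experimental=True` only;
  they belong to an earlier dispersion/polarization parameterization and
  are not consistent with the XDM terms computed here.
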