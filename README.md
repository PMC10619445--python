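# ce1p

Pairwise quantum-mechanical intermolecular interaction energies for
molecular dimers and crystals, without a dimer SCF.

## What this is for

Rationalizing and predicting intermolecular interactions in molecular
crystals — hydrogen bonds, stacking, halogen bonds, packing energetics —
needs dimer interaction energies that are cheap enough to evaluate for
dozens to hundreds of neighbour pairs, yet retain quantum-mechanical
physics.  The conventional route (full SCF on the dimer *AB* and both
monomers, `E_int = E_AB − E_A − E_B`) costs three SCF calculations per pair
and suffers basis-set superposition error.

This package implements the *CE model* family instead: each monomer's
wavefunction is computed **once**, re-used under rigid rotations and
translations (crystal symmetry), and the interaction energy of a pair is
assembled from five physically distinct components computed from the two
frozen monomer wavefunctions:

```
E_tot = k_coul·E_coul + k_exch·E_exch + k_rep·E_rep + k_pol·E_pol + k_disp·E_disp
```

* **E_coul** — classical electrostatics between the two frozen total charge
  distributions (exact long-range multipole behaviour);
* **E_exch** — inter-monomer Hartree–Fock exchange of the frozen densities;
* **E_rep** — the energy rise caused by a single symmetric (Löwdin)
  orthonormalization of the superposed occupied orbitals — the only step in
  which the monomers "respond" to each other;
* **E_pol** — −½ Σᵢ αᵢ |**F**(rᵢ)|², with atom-in-molecule polarizabilities
  αᵢ = α′ᵢ·Vᵢ/V′ᵢ from XDM Hirshfeld volumes and the partner's electric
  field at the nuclei;
* **E_disp** — exchange-hole dipole moment (XDM) dispersion: Becke–Roussel
  hole dipoles → atomic ⟨M₁²⟩,⟨M₂²⟩,⟨M₃²⟩ moments → pairwise C₆/C₈/C₁₀ →
  damped −Σₙ Cₙ/(rⁿ + R_vdWⁿ) with R_vdW = a₁·R_crit + a₂
  (a₁ = 0.65, a₂ = 1.70 Å).

The scale factors define the models: **CE-1p** (a single parameter,
k_rep = k_pol = 0.78, everything else unscaled — transferable across
wavefunction sources), **CE-2p** (k_exch-rep = 0.485, k_pol = 0.803) and
**CE-5p** (five method-specific factors fitted under bounds).  The fitting
procedures themselves (k-scan, two-parameter minimum, bounded least
squares) are part of the package (`ce1p.fitting`).

For crystals, the package reads CIF, extracts whole molecules across
periodic boundaries, enumerates symmetry-unique neighbour dimers with
multiplicities, and sums pair energies directly:
`E_lat = ½ Σ multiplicity × E_tot`.  Polarization can alternatively be
evaluated in *crystal-field* mode, where the vector fields of all
neighbours are summed **before** squaring — the physically correct
many-body form, which matters greatly for ionic systems.

Everything is self-contained: a built-in restricted Hartree–Fock engine
(McMurchie–Davidson integrals, numba-accelerated) with a generated
split-valence-polarization basis serves as the in-process wavefunction
provider; orbitals from external engines can be supplied as pure-spherical
Molden files.

## Worked example

```bash
ce1p fixtures --out fx                 # generated inputs, no downloads
ce1p dimer fx/water_a.xyz fx/water_b.xyz
```

For the built-in hydrogen-bonded water dimer with HF monomer wavefunctions
this prints (abridged):

```
"components_kjmol": {
 "e_coul": -38.72, "e_exch": -33.44, "e_rep": 59.95,
 "e_pol": -4.94,  "e_disp": -2.05
},
"total_kjmol": -31.29
```

Reading: electrostatics (−38.7 kJ/mol) dominates the attraction, exchange
(−33.4) and orthogonalization repulsion (+59.9) largely cancel into a net
short-range wall, polarization and dispersion add a few kJ/mol each; with
the CE-1p factor 0.78 on repulsion+polarization the scaled total is
−31.3 kJ/mol, a bound hydrogen-bonded pair (HF monomer charges
over-polarize the dimer; hybrid-DFT orbitals via Molden input give weaker
binding).  The Löwdin charge-transfer diagnostic (|Δq| ≈ 0.02 e, threshold
0.33 e) confirms the pair is safely within the model's no-charge-transfer
regime.

Other entry points: `ce1p lattice crystal.cif --pol-mode both`,
`ce1p fit table.csv --model 1p`, `ce1p xdm-report molecule.xyz`.

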