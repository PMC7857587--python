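# Methods

## Model overview

The package predicts two spin-label observables from a protein structure or
conformational ensemble using the rotamer-library approach (RLA): the
electron–electron distance distribution and dipolar time trace measured by
DEER/PELDOR, and the transverse paramagnetic relaxation enhancement (PRE)
Γ₂ with the derived HSQC intensity ratio. The probe is never simulated
explicitly; its conformational ensemble at a site is approximated by a
fixed library of conformers with intrinsic Boltzmann probabilities p_int,
reweighted in situ by a steric energy against the frozen protein frame.
This assumes (i) probe motion is rotameric — well described by a discrete
set of states; (ii) probe–protein interaction is purely steric (no
electrostatics or solvation); and (iii) the probe equilibrates much faster
than the protein's conformational exchange, so rotamer averaging happens
within a frame and protein averaging across frames.

## Rotamer placement and steric weighting

Library conformers are stored in a common canonical backbone frame and are
not re-canonicalized on load: each conformer's own (N, Cα, C) triad is
superposed onto the site's triad by an equal-weight three-point
least-squares fit (SVD with reflection excluded), so any internally
consistent library frame works.

The external energy of conformer i is a 6-12 Lennard-Jones sum over
probe-heavy-atom × protein-heavy-atom pairs within a 1 nm cutoff, with
Lorentz–Berthelot combination and the pair σ scaled by `sigma_scaling`
(default 0.5), converted to kT at the run temperature (default 298 K). Two
choices deserve notice:

* **Environment set.** The labelled residue's side chain is excluded (it is
  conceptually replaced by the probe) while its backbone N, Cα, C, O stay.
  The probe's *own* triad atoms are excluded from the energy pairs: after
  superposition they coincide with that same backbone and would otherwise
  always register as a hard clash. For two-label DEER runs each site is
  evaluated independently, ignoring the other site's rotamers.
* **Attractive tails are kept.** The full 6-12 form is used, so ε_ext can be
  negative and Z can slightly exceed 1; Z is bounded by exp(−min ε_ext).
  Implementations that clamp at zero will give slightly smaller weights for
  surface sites.

Energies above 700 kT are treated as +∞ (weight exactly 0) to avoid
underflow ambiguity. If every rotamer clashes, Z = 0 and the site's
probabilities are undefined for that frame; such frames are excluded
downstream by the Z cutoff (default 0.05, user-settable), which also
discards frames where the probe fits only marginally.

The default LJ table is element-keyed (C, N, O, S) with representative
CHARMM36-like ε, σ values; full per-type force-field assignment is out of
scope and a user table can override per library or protein.

## DEER back-calculation

Per frame, all R_A × R_B pair distances between the two sites' paramagnetic
centers (N–O bond midpoints — the symmetric choice; the alternative of
using the N atom shifts centers by < 0.1 nm) are deposited with weight
p_i·p_j into half-open bins of width dr = 0.05 nm on [0, 12] nm (bin
centers reported). Pairs beyond r_max are dropped with a logged warning.
Frame histograms are averaged with uniform or user-supplied weights after
the Z cutoff, and the Gaussian low-pass filter (default σ = 0.05 nm) is
applied once, after frame averaging, as a discrete unit-sum kernel
truncated at 6σ with renormalization to unit integral — numerically
equivalent to the Fourier-domain formulation for interior grids.

The dipolar kernel uses the Fresnel-integral closed form of the powder
average ∫₀¹ cos((3x²−1)ωt) dx with ω = (μ₀/4π) g² μ_B²/(ħ r³), CODATA 2018
constants and g = 2.0023; it is validated against adaptive quadrature of
the defining integral to < 1e-6 (in practice ~1e-15). S(t) is the
probability-weighted kernel sum over occupied bins at their centers — the
natural quadrature for a histogram density, making S(0) = 1 exact for a
unit-integral P(r). The time grid is 0.01–5.5 μs in 0.01 μs steps,
endpoints included. V(t) = 1 + λ(S−1) with λ restricted to [0.02, 0.5];
λ can be fitted to an experimental form factor by the closed-form
least-squares estimator (predicted S linearly interpolated onto the
experimental time base, result clipped to the admissible range with a
warning). When neither a fixed λ nor a trace to fit is provided, the
written V(t) uses the maximal admissible depth 0.5 and the run manifest
records it.

## PRE back-calculation

For each backbone amide proton (atom name `H`, `HN` accepted; the labelled
residue excluded; prolines and N-termini skipped and recorded), each frame
yields ⟨r⁻³⟩, ⟨r⁻⁶⟩ and the order parameters

    S²_radial  = ⟨r⁻³⟩² / ⟨r⁻⁶⟩
    S²_angular = Σ_ij (3/2 cos²Ω_ij − 1/2) p_i p_j

with Ω_ij the angle between the proton→center displacement vectors of
rotamers i and j. S² = S²_radial·S²_angular enters the model-free spectral
density J(ω) = ⟨r⁻⁶⟩[S²τ_c/(1+ω²τ_c²) + (1−S²)τ_t/(1+ω²τ_t²)], and

    Γ₂ = (1/15)(μ₀/4π)² γ_I² g² μ_B² s_e(s_e+1) [4J(0) + 3J(ω_I)]

with γ_I = 2.67522187×10⁸ rad s⁻¹ T⁻¹ and s_e = 1/2. The interface takes
(τ_c, τ_t) directly — defaults 2 ns and 0.2 ns, with t_d = 10 ms,
R₂,dia = 12.6 s⁻¹, ν_I = 750 MHz — since users typically hold these
effective times; the decomposition 1/τ_c = 1/τ_r + 1/τ_s and
1/τ_t = 1/τ_c + 1/τ_i is documented for those starting from the protein
tumbling time τ_r and internal time τ_i. τ_t ≤ τ_c is enforced.

Averaging order follows the fast-label assumption: order parameters and Γ₂
are computed within each frame, then ⟨Γ₂⟩ = Σ_k w_k Γ₂,k across Z-filtered,
renormalized frames. Sites excluded in every frame yield NaN (explicit
missing values, never silent zeros), which propagate to the intensity
ratio I_para/I_dia = R₂,dia exp(−⟨Γ₂⟩ t_d)/(R₂,dia + ⟨Γ₂⟩). The t_d in the
exponent is taken verbatim as the total INEPT evolution time.

The Cβ comparison mode places a single-point electron at the labelled
residue's Cβ (glycine rejected), forcing S² = 1 so only τ_c matters; no
steric evaluation is performed and Z is recorded as 1 for every frame.

## Synthetic data

The fixture generators produce everything the pipelines consume, so the
full method is testable without downloads:

* **Backbones** are ideal poly-alanine helices or extended chains built
  from standard internal coordinates (φ/ψ = −57/−47 or −120/120, ω = 180),
  with amide H and Cβ placed geometrically.
* **Toy rotamer libraries** carry the canonical triad, one arm carbon and a
  nitroxide N–O pair whose midpoint sits at a controlled arm length
  (default 0.7 nm from Cα, the scale of an extended MTSSL side chain) along
  seeded random or explicitly specified directions.
* **Two-state trajectories** place two label sites with *identically
  oriented* triads, so superposition reduces to a translation and the
  center–center distance equals the Cα–Cα separation exactly — giving
  analytically known P(r) masses and peak positions for end-to-end checks.
* **Synthetic form factors** are V = 1 + λ(S−1) plus seeded Gaussian noise.

What these fixtures do *not* emulate: real probe chemistry and force-field
typing, correlated probe–protein motions, conformational strain at buried
sites, experimental background and noise structure. Passing tests therefore
validate the placement/weighting/back-calculation mathematics and the
ensemble bookkeeping, not the chemical accuracy of any particular library.

## Numerical choices and limitations

* Histogram bins are half-open [k·dr, (k+1)·dr); distances exactly on a
  boundary follow floating-point floor. Unit integral is preserved exactly
  through averaging and filtering (asserted to 1e-9).
* The kernel's t → 0 limit is handled analytically (K = 1 below
  ωt < 1e-12); |K| is clipped to 1 against rounding.
* Per-frame data (histograms or Γ₂ rows, plus Z) are stored in HDF5 so
  ensemble averages can be recomputed under new weights without re-placing
  rotamers; streaming and batch recomputation agree exactly.
* Coordinates are nm internally; file formats keep their native Å. PDB
  coordinate precision (0.001 Å) limits bundle round-trips to ~1e-4 nm.
* Insertion codes are unsupported; residue numbering follows the input
  file, and ambiguous residue numbers across chains must be disambiguated
  by an explicit chain ID (no silent first match).
* Not covered by design: library construction from MD clustering, Bayesian
  reweighting of rotamer weights, intermolecular-background correction or
  any inversion of traces to P(r), longitudinal PRE, non-proton nuclei, and
  electrostatic or solvation contributions to the placement energy.

Test problem sizes (≤ 46 rotamers, ≤ 30 residues, ≤ 20 frames) keep the
whole suite and the acceptance script in the seconds range while exercising
every code path; the mathematics is size-independent.
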