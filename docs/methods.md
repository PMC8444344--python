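# Methods

`saptmc` computes the interaction energy of a weakly bound dimer as a sum
of physically defined components — symmetry-adapted perturbation theory
(SAPT) through second order in the intermolecular operator — for monomers
described by multiconfigurational wave functions (CASSCF, state-averaged
CASSCF, GVB perfect pairing, restricted HF, and exact FCI for two-electron
monomers).  This note records the model, the working equations as this
package derives and implements them, the numerical choices, and the known
limitations.

## Model

For monomers A (state I) and B (state J) with product reference
|Ψ_I^A Ψ_J^B⟩, the symmetrized Rayleigh–Schrödinger expansion in the
intermolecular Coulomb operator V̂ gives, through second order,

    E_int = E_elst(1) + E_exch(1) + E_ind(2) + E_exch-ind(2)
          + E_disp(2) + E_exch-disp(2).

All exchange components use the single-exchange (S²) approximation: the
intermonomer antisymmetrizer is truncated after single transpositions,
𝒜 ≈ 1 − P̂₁.  Both monomers must be closed-shell singlets (possibly
electronically excited); the dimer reference must be nondegenerate.

Every component is evaluated from monomer one- and two-particle (transition)
reduced density matrices; the dimer wave function is never computed.

## Working equations and how they were validated

The published formulation fixes the *contracts* of the working equations
(built solely from 1-/2-RDMs; determinantal limits; symmetry properties).
The explicit contraction formulas used here were re-derived from first
principles and anchored to independent brute-force oracles rather than
transcribed:

* **Master S² matrix elements.**  For singlet monomers, every matrix
  element ⟨bra_A bra_B| Ô P̂₁ |ket_A ket_B⟩ factorizes into spatial
  contractions of monomer (transition) densities with a universal spin
  factor ½ per exchanged pair.  For two-electron monomers the densities
  are explicit geminal amplitude matrices and all patterns reduce to
  matrix traces plus four Coulomb-tensor contractions (`contractions.py`);
  for general monomers they are contractions of the spin-summed 1-RDM and
  2-RDM kernels (`first_order.py`).  Both paths agree to machine precision
  with explicit tensor algebra — wave functions represented with one
  spin-orbital axis per electron, P̂₁, the full antisymmetrizer, and V̂
  applied literally (`oracles.py`, exercised up to six electrons).

* **Second order.**  Induction and dispersion are sums over monomer
  transitions: E_ind(A←B) = −Σ_μ |⟨0|Ω̂_B|μ⟩|²/ω_μ with Ω̂_B the partner's
  electrostatic-embedding potential (nuclei + unperturbed density), and
  E_disp = −Σ_{μν} |Σ γ^μ v γ^ν|²/(ω_μ+ω_ν).  The exchange counterparts
  use the combination ⟨0|(V̂ − E_elst)(P̂₁ − ⟨P̂₁⟩)|Ψ^(1)⟩ with the
  first-order induction/dispersion wave functions.  For exchange–induction
  the amplitude sum is linear, so it collapses into a single "response
  geminal" (or response transition density) and one master-contraction
  call per direction; exchange–dispersion keeps the double transition sum,
  with each S² pattern evaluated as one large matrix product over a
  rank-projected Coulomb tensor (every intermediate has its first index in
  the reference geminal's column space; natural-expansion coefficients
  below 1e-5 are dropped, which is exact to ~1e-10 in the energies).
  All four second-order components were verified to machine precision
  against explicit sum-over-states Rayleigh–Schrödinger theory with
  literal operator algebra.

* **Linear response (ERPA).**  Transition energies and densities of a
  correlated monomer come from the equation-of-motion ansatz with single
  (de-)excitation operators over the orbital pairs (p,q), q inactive or
  active, p active or virtual:  [A B; B A](X,Y) = ω(N, −N)(X,Y), with
  A,B double-commutator expectation values assembled from the diagonal
  1-RDM and the occupied-block 2-RDM, and the diagonal metric
  N = 2(n_q − n_p).  The matrix builder was verified element-by-element
  against literal ⟨Ψ|[E†,[Ĥ,E]]|Ψ⟩ operator algebra on embedded CI
  vectors, and reduces exactly to singlet RPA/TDHF for a determinant
  reference.  Active pairs whose relative occupation gap is below 1e-6
  (CAS) or 1e-2 (GVB) are discarded — they carry a (near-)singular metric.
  The generalized problem is solved in the symmetric reduced form when the
  Hessians are positive definite (stable ground states) and by a dense
  generalized solver otherwise; complex eigenvalues raise an instability
  error naming the state (no extrapolation workaround is attempted).

* **Transition densities.**  1-TRDMs follow the metric form
  ⟨0|E_qp|ν⟩ = N_pq X^ν_pq, ⟨0|E_pq|ν⟩ = −N_pq Y^ν_pq.  For two-electron
  monomers the full excited geminal O†_ν|0⟩ is reconstructed explicitly,
  which makes every two-particle transition quantity exact at the
  ERPA-amplitude level; exchange terms use these geminals while
  polarization terms use the metric-form TRDMs (the two conventions
  coincide in the exact-response limit and differ at the quasi-boson
  level otherwise).  For larger monomers the transition 2-RDM is
  approximated by the product factorization that is exact in the
  single-determinant limit; exchange–dispersion for such monomers is not
  implemented (the in-scope systems have two-electron monomers, and at the
  HF level the geminal path covers them).

* **Excited monomers.**  Second-order sums run over positive transitions
  only; the missing de-excitation content ε^{I→J} is restored from ERPA
  solutions of each lower state J < I, where the J→I transition appears
  with positive energy: ε_ind = +|⟨Ω⟩|²/ω_I^{(J)} ≥ 0 and
  ε_disp = −Σ_ν |W_ν|²/(ω_ν^{B} − ω_I^{(J)}).  The J→I root is identified
  by energy ordering with a cross-check against the state-energy gap; a
  mismatch raises a diagnostic.  With exact response properties the
  positive+ε route equals the signed full-spectrum sum to machine
  precision (tested); a `negative_transitions` switch reproduces the
  uncorrected variant.  Singly excited two-electron states have half-filled
  degenerate occupations; their de-excitation pair is metric-singular and
  the package deliberately raises rather than returning a silent zero.

* **Hybrids.**  δ_HF = E_int^HF(CP) − (E_elst + E_exch + E_ind +
  E_exch-ind)@HF estimates induction beyond second order; it is attached
  only when the induction share of the total exceeds 12.5%.  CAS+DISP adds
  the SAPT dispersion (including ε_disp for excited states) to the
  counterpoise-corrected supermolecular CASSCF interaction energy.

## Embedded quantum-chemistry engine

All monomer and supermolecular wave functions are produced in-package:

* McMurchie–Davidson Gaussian integrals (spherical harmonics through d
  functions; numba-compiled), with correlation-consistent basis data for H
  and He embedded as text.  Validated against published RHF/FCI energies
  (He and H2 in cc-pVDZ/cc-pVTZ to ~1e-6 hartree) and structural
  invariants (translation invariance, loop-contraction cross-checks).
* Restricted HF with DIIS; canonical orthogonalization guards near-linear
  dependence in augmented dimer basis sets.
* Determinant FCI (general, small spaces) cross-checked against an exact
  operator-algebra Hamiltonian construction; a singlet pair-space solver
  for two-electron systems (symmetry-blocked full diagonalization yields
  the complete state set used by the benchmark oracle); and a dedicated
  four-electron FCI whose sigma vector is evaluated as blocked matrix
  products over irrep-ordered orbital pairs (Davidson, monomer-product
  start vector, spin symmetrization).
* CASSCF by direct minimization: an exact variable-projection optimizer
  for two-electron systems (the active-space energy is an eigenvalue of
  the projected pair Hamiltonian; analytic Hellmann–Feynman gradients) and
  a general small-scale optimizer (L-BFGS over nonredundant rotations,
  generalized-Fock gradient, singlet-selected state averaging with equal
  weights).  Both paths agree to 1e-8 hartree where they overlap, and
  gradients were verified against finite differences.
* Abelian point-group handling: for dimers oriented with symmetry planes
  on coordinate planes, all C2v operations are axis sign flips, giving
  exact two-bit irrep labels that block the large diagonalizations.

Counterpoise correction is applied to every supermolecular energy; all
monomer calculations use the dimer-centered basis (partner centers as
ghosts).  This is the only supported mode.

## The benchmark model system

The synthetic test system is the T-shaped H2···H2 dimer of the
bond-dissociation benchmark: one monomer fixed at R = 1.44 a0, the other
stretched from 1.37 to 7.20 a0, aug-cc-pVTZ.  The stretched monomer is
perpendicular to the intermonomer axis and bisected by it.  The printed
"intermolecular distance 6.21 a0" is interpreted as the distance between
the nearest atoms of the two monomers, held fixed along the stretch
(midpoint distance 0.72 + sqrt(6.21² − (R/2)²)); this protocol keeps the
interacting atoms at constant range while the covalent bond breaks, and it
reproduces the published SAPT-vs-supermolecular-FCI deviation at the
equilibrium bond length (1.15% computed vs 1.1% printed).  Both the
bond-midpoint convention and the on-axis orientation are available as
options; under no examined convention does the deviation at R = 7.2 a0
reach the published 15% (computed values range from 3% to 12% depending on
convention and basis), and the stretched-endpoint comparison is reported
as computed.  What passing the model-system tests shows: the method
reproduces exact two-electron benchmarks for a genuinely multireference
dissociation problem.  What it does not show: accuracy for many-electron
monomers, where intramonomer correlation is only partially recovered.

## Numerical choices

* Internal units hartree/bohr; tables print milli-hartree to 3 decimals.
* Occupation thresholds: GVB strong-occupation boundary 0.992; pair
  degeneracy filters 1e-2 (GVB) / 1e-6 (CAS); metric zero tolerance 1e-10;
  positive-eigenvalue classification 1e-8 (all overridable).
* Natural orbitals: descending occupation; degenerate-eigenvector phases
  fixed by making the largest-magnitude coefficient positive.  No energy
  depends on these phases (tested).
* Transition caps: the FCI oracle uses the complete monomer state set for
  polarization sums; second-order exchange sums are truncated at the 1200
  lowest transitions (their amplitudes decay quickly; the truncation
  affects totals below the micro-hartree scale at the benchmark
  geometries).
* Four-electron FCI: Davidson to residual 1e-5 (energies converged far
  tighter), subspace collapse at 8 vectors to bound memory; the production
  dimer calculation peaks near 5 GB.
* Benchmark problem sizes: the bundled acceptance script scans four
  stretch points (1.37, 1.41, 4.5, 7.2 a0) and runs the
  supermolecular FCI at the two printed comparison points; the test suite
  uses two stretch points.  These sizes were chosen so a full
  reproduction runs on a single CPU in well under an hour.

## Known limitations

* Closed-shell singlet monomers only; no open-shell or high-spin coupling.
* Exchange strictly at the S² level (measured against the full
  antisymmetrizer on the benchmark system: differences below 1e-6
  hartree at all examined geometries, so this is not a practical
  limitation there).
* GVB for monomers with more than two electrons is accepted only through
  the HDF5 loading interface (no internal GVB-PP solver); for two-electron
  monomers GVB ≡ CAS(2,2) and is computed directly.
* Exchange–dispersion requires explicit transition geminals and is
  therefore limited to two-electron monomers; exchange–induction for
  larger monomers uses the determinant-limit 2-TRDM factorization.
* The embedded engine ships H and He basis data (through d functions);
  heavier elements require externally supplied monomer data.
* ERPA includes orbital response only (no CI-coefficient response), and
  near-instabilities of excited-state references raise errors rather than
  being extrapolated through.
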