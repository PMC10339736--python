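# Methods

## Model and scope

The package computes vertical ionization potentials (VIPs) and vertical
electron affinities (VEAs) of closed-shell molecules at the double-hybrid
(DH) density-functional level.  A DH functional mixes exact exchange
(fraction α_X, possibly range-separated with parameter ω) into the
self-consistent reference and adds a scaled second-order perturbative
correlation correction on top of the converged orbitals.  For charged
excitations the first-order (hybrid-level) problem is diagonal in the space
of singly ionized/attached determinants, so hybrid functionals simply
return (the negative of) orbital energies; everything beyond that is the
second-order machinery implemented here.

Two ansätze share the same intermediates:

* **CIS(D)-type (perturbative).**  The (D) correction to the Koopmans value
  is the diagonal, frequency-independent second-order self-energy of the
  target orbital, evaluated at its own orbital energy.  Because the
  frequency is pinned to ε_target, the 2p1h denominators coincide with
  ground-state MP2 pair denominators, and the whole correction is a set of
  N⁴ contractions (one index fixed to the target).  The disconnected
  second-order terms cancel against the ground-state MP2 energy and are
  never formed.

* **ADC(2)-type (iterative, non-Dyson).**  The singles (1h or 1p) vector is
  relaxed against the doubles (2h1p or 2p1h) space.  The doubles block is
  never stored: its effect is folded analytically into the singles
  operator, σ(c, ω) = diag(∓ε)c + S c + F(ω) c, where F(ω) is the fold of
  the explicit doubles coupling and S is the *static* second-order singles
  block — the complementary particle-hole sector folded at the reference
  orbital energies (for ionization, the 2p1h sector; for attachment, the
  2h1p sector).  On the diagonal, S + F reproduce the perturbative
  correction exactly when ω equals the Koopmans value and the vector is a
  unit vector, which is the content of the continuity (Richardson) test:
  iterative and perturbative results agree to first order in the
  second-order coupling.

Ionization and attachment are treated independently (non-Dyson): the IP
problem lives entirely in occupied-indexed intermediates and requires no
virtual–virtual integrals; the EA problem reaches the virtual–virtual
block only through single-fixed-index slices.

## Spin scaling

Every second-order quantity is resolved into opposite-spin (OS) and
same-spin (SS) parts and recombined as c_OS·X_OS + c_SS·X_SS.  In
closed-shell spatial orbitals the OS kernel is the squared direct integral
and the SS kernel the direct-times-antisymmetrized product; the split is
validated configuration by configuration against spin-orbital oracles
(a configuration is same-spin when all its summed spins match the
target's).  A global single-parameter DH is c_OS = c_SS = α_C; SOS
functionals set c_SS = 0.  The SOS case is realized by weight — the
Laplace-transform N⁴ reformulation is intentionally not implemented, as the
standard contraction is already N⁴ for the perturbative corrections and the
folded iterations.

In the folded operator the scales multiply the doubles *products*;
equivalently, the unfolded secular matrix carries couplings scaled by
√c per spin class (this is the form the dense oracle diagonalizes, so both
routes represent the same matrix).

## Pole strength

For the iterative ansatz the doubles amplitudes of a converged state are
d = (ωI − D)⁻¹ Ũᵀ c, so ‖d‖² equals −⟨c| dF/dω |c⟩ and the pole strength is
p = 1/(1 + ‖d‖²) — the squared singles-block norm of the normalized full
vector.  With zero scales p = 1 exactly, as for the perturbative ansatz,
where the (D) term is an energy-only correction.  This normalization (the
scaled unfolded matrix's eigenvector norm partition) is one consistent
reading of how the scaling rule acts on the spectroscopic amplitudes; it is
identified as such in the report metadata
(`pole_strength_convention`).

## Solver

The nonlinear problem σ(c, ω) = ωc is solved by macro-iterations: freeze ω,
run a Davidson eigensolver on the symmetric frozen-ω operator, update ω to
the followed Ritz value, repeat until |Δω| ≤ `conv_energy`
(default 1e−6 E_h, the energy threshold used throughout) *and* the residual
‖σ(c) − ωc‖ is below `resid_tol` (default 1e−5, chosen to under-resolve the
energy threshold).  Root following selects, at every subspace
diagonalization, the Ritz vector of maximum overlap with the anchor — the
target's Cartesian unit vector initially, the previous macro-iterate after
the first pass.  An overlap below 0.3 raises a root-lost error rather than
silently switching states.  Subspace limits: 20 vectors, deterministic
two-pass Gram–Schmidt, collapse to the followed root plus the anchor.
The diagonal preconditioner uses the first-order diagonal plus the static
block, with denominators clamped at 1e−2 E_h.

Degenerate or resonant denominators (pair denominators, 2h1p/2p1h shifts,
or folded ω-denominators) smaller than 1e−8 E_h abort with a
quasi-degenerate-reference error; no level shifting is applied, since the
formalism assumes a gapped single-reference regime.

## Density fitting

K = J·Jᵀ with J = I·V^(−1/2).  The auxiliary metric is conditioned by
symmetric eigendecomposition; eigenvalues below 1e−10 (relative) are
dropped, which makes exactly redundant auxiliary functions harmless (the
projection onto the auxiliary span is unchanged).  The symmetric inverse
square root, not a Cholesky factor, is used so J is the plain
metric-orthonormalized factor.  The auxiliary index is stored
fastest-varying because every hot contraction sums over it.  All production
contractions run through one instrumented `einsum` wrapper that accumulates
the loop-nest cost estimate (product of distinct index extents); the
cost-scaling checks fit the log–log slope of this counter across a
proportional size ladder and compare with the nominal
N_occ²·N_virt·N_aux growth of the VIP correction.

## Units and conventions

Energies are hartree internally; eV appears only at the reporting boundary
(1 E_h = 27.211386245988 eV, CODATA 2018).  Orbital energies ascend within
the occupied and virtual blocks, ties keeping backend order (stable sort).
The EA channel natively reports attachment energies (+ε_c + correction);
the `ea_sign: ea` option flips the sign at the reporting boundary.  Frozen
cores follow the standard chemical-core count per element under the `auto`
policy (`none` correlates everything, an integer freezes exactly that
many).  The (D) denominators for DH references use the DH orbital energies
as they come — no level shift — which is the plain reading of the working
equations; RS-DH second-order terms default to full-range integrals, with
an attenuated-metric hook left on the adapter contract for backends that
provide range-separated integrals.

## Synthetic references and what the tests show

`dhipea.fixtures.make_toy` draws deterministic synthetic references
(`numpy.random.default_rng`, PCG64): occupied energies uniform in
[−1.0, −0.7] E_h, virtuals in a 0.3 E_h band starting `gap_min` above the
HOMO, and symmetric three-center factors of scale σ = 0.05.  The fixture
suite uses `gap_min` = 0.8 E_h: with narrow bands and a wide gap every
1h/1p root lies outside the 2h1p/2p1h quasi-continuum, folded denominators
stay bounded away from zero, and second-order corrections remain small
against the gap — the single-root-dominant regime the methods are designed
for, and the regime in which root following is well defined.  Fragmented
toys replicate one fragment block-diagonally (orbitals re-sorted by energy
with a stable permutation), giving exactly zero cross-fragment integrals;
these anchor the size-intensivity checks.

The toys emulate the algebraic structure of a correlated reference —
gapped spectrum, factorized PSD integrals, fragment separability — but not
basis-set structure, integral sparsity, point-group symmetry, or the
near-degeneracies of real valence spectra.  Passing tests therefore
establish the correctness of the implemented equations and solver against
independent dense oracles, not the chemical accuracy of any functional;
accuracy on real molecules is a property of the functional and the SCF
backend, which this package deliberately treats as inputs.

The dense oracles are an independent code path: antisymmetrized
spin-orbital integrals built directly from the raw factors, explicit
configuration sums for the self-energy, and full diagonalization of the
unfolded singles⊕doubles matrix for the iterative ansatz (size-guarded to
occ ≤ 6, virt ≤ 8).  Oracle agreement is exercised over dozens of seeded
toys at 1e−10 E_h (perturbative) and 1e−6 E_h (iterative, the solver's own
energy threshold).

## Functional registry

The registry (`dhipea/data/functional_registry.yaml`, version 1) fixes for
each of the twelve assessed functionals its class, empirical-parameter
count, ingredients, and scaling parameters, each entry carrying its
citation.  Entries whose numeric mixing parameters could not be verified
against the original papers during packaging are flagged
`approximate: true`; the class and parameter-count fields, which the tests
check, are definitive.  Tests always pass scales explicitly, so no shipped
result depends on an approximate entry.

## Known limitations

* Closed-shell (restricted) references only; no open-shell, relativistic,
  or solvated variants.
* No real SCF backend is bundled; the adapter contract plus the synthetic
  backend stand in, and XC evaluation/grids are entirely delegated.
* Pole strengths use the normalization above; other readings of the
  scaling rule for spectroscopic amplitudes would differ at second order.
* The iterative solver targets singles-dominant roots; states embedded in
  the doubles quasi-continuum (shake-up-dominated) are outside the design
  envelope and will typically raise root-lost or degeneracy errors.
* The perturbative problem sizes used in the shipped verification suites
  (up to ~12 occupied / 18 virtual toy orbitals) were chosen to keep the
  dense oracles cheap; the production code paths themselves are
  dimension-agnostic.
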