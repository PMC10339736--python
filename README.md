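# dhipea

Direct calculation of **vertical ionization potentials (VIPs)** and
**vertical electron affinities (VEAs)** with double-hybrid (DH) density
functionals, on top of a pluggable self-consistent-field reference and
density-fitted (DF) two-electron integrals.

## Who this is for

Method developers and computational chemists who want the DH route to
charged excitations — orbital energies corrected by a scaled second-order
term — without running Δ-style total-energy differences.  Two ansätze are
implemented:

* **Perturbative (CIS(D)-based).**  The first-order problem in the space of
  singly ionized (attached) determinants is diagonal: the VIP of occupied
  orbital *k* is −ε<sub>k</sub>, the attachment energy of virtual *c* is
  +ε<sub>c</sub>.  The second-order (D) correction evaluated at the target
  orbital energy equals the diagonal, frequency-independent second-order
  self-energy of that orbital.  In closed-shell spatial orbitals,

  Σ<sub>2p1h</sub>(k) = Σ<sub>iab</sub> (ka|ib)[2(ka|ib) − (kb|ia)] / (ε<sub>k</sub>+ε<sub>i</sub>−ε<sub>a</sub>−ε<sub>b</sub>),
  Σ<sub>2h1p</sub>(k) = Σ<sub>ija</sub> (ki|aj)[2(ki|aj) − (kj|ai)] / (ε<sub>k</sub>+ε<sub>a</sub>−ε<sub>i</sub>−ε<sub>j</sub>),

  and the DH result is VIP = −ε<sub>k</sub> − (c<sub>OS</sub>Σ<sup>OS</sup> + c<sub>SS</sub>Σ<sup>SS</sup>),
  with (c<sub>OS</sub>, c<sub>SS</sub>) the functional's opposite-/same-spin
  weights (a global DH has c<sub>OS</sub> = c<sub>SS</sub> = α<sub>C</sub>;
  SOS variants set c<sub>SS</sub> = 0).  All contractions are *N*⁴ because
  one index is pinned to the target orbital, and the ionization path never
  touches virtual–virtual integrals.

* **Iterative (non-Dyson ADC(2)-based).**  The 1h (1p) singles vector is
  relaxed against the 2h1p (2p1h) doubles space, which is folded in
  analytically: σ(c, ω) = diag(∓ε)c + [S + F(ω)]c with a static
  second-order singles block S and the ω-dependent fold F.  The nonlinear
  problem σ(c, ω) = ωc is solved by a Davidson eigensolver with
  maximum-overlap **root following** inside macro-iterations that update ω
  to 10⁻⁶ E<sub>h</sub>.  The single *N*⁵ precompute is done once per job
  regardless of the number of states; each iteration is *N*⁴.  Pole
  strengths (squared singles-block weight of the full state vector) are
  available for this ansatz; the perturbative one has pole strength 1 by
  construction.

Integrals enter through the DF factorization **K = J·Jᵀ** with
J = I·V^(−1/2) (three-center integrals times the inverse metric square
root), built block-selectively: occupied–occupied and occupied–virtual
blocks are materialized, virtual–virtual factors exist only as on-demand
single-index slices.

The twelve benchmark functionals (spin-scaled range-separated and
long-range-corrected DHs, global DHs, and hybrids) ship in a versioned
registry; hybrids report bare orbital energies, which is exact at first
order for them.

No real SCF engine is bundled: any backend satisfying the small adapter
contract (converged closed-shell MOs plus AO Coulomb integrals) plugs in,
and a seeded synthetic backend plus dense brute-force oracles make every
stage testable offline.

## Worked example

A job file over the synthetic backend (4 occupied, 6 virtual, 20 auxiliary
functions, seed 7), solving two ionized and two attached states with the
iterative ansatz and scales (c_os, c_ss) = (1.3, 0.4):

```yaml
# job.yaml
functional:
  name: demo-dh
  family: global_DH
  alpha_x: 1.0
  c_os: 1.3
  c_ss: 0.4
  ansatz: adc2
  n_empirical_params: 0
method: adc2
channel: both
n_states: 2
backend: toy
toy: {n_occ: 4, n_virt: 6, n_aux: 20, seed: 7, gap_min: 0.8}
```

```text
$ dhipea run --config job.yaml
ip  orbital   3  omega1    19.8871 eV  final    19.9777 eV  niter   3  pole 0.9965
ip  orbital   2  omega1    20.8791 eV  final    20.8943 eV  niter   3  pole 0.9948
ea  orbital   0  omega1     1.9250 eV  final     1.8723 eV  niter   3  pole 0.9945
ea  orbital   1  omega1     4.3324 eV  final     4.2661 eV  niter   3  pole 0.9938
```

`omega1` is the Koopmans (orbital-energy) value, `final` the scaled
second-order result after self-consistent relaxation: the correction raises
the VIPs slightly and lowers the attachment energies here, and the pole
strengths just below 1 show the states remain strongly single-configuration.
`--output report.json` (or `--format tsv`) writes the structured report;
`--ea-sign ea` flips the attachment channel to the electron-affinity sign
convention.  The same jobs are available programmatically through
`dhipea.run_job`.

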