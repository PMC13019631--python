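# Methods

This note documents the model, the numerical choices, and the limits of what
the test fixtures can show. All quantities are in atomic units (hartree,
bohr) unless stated.

## The correction being computed

For a closed-shell RHF reference with canonical orbitals, the explicitly
correlated correction to the MP2 energy in the fixed-amplitude (3C/FIX)
ansatz is assembled from three pair-summed intermediates over active
occupied pairs (i, j):

    V_kl^ij = <ij| F12 Q12 g12 |kl>
    X_kl^ij = <ij| F12 Q12 F12 |kl>
    B_kl^ij = <ij| F12 Q12 (f1 + f2) Q12 F12 |kl>

with the Slater-type geminal F12 = -exp(-gamma r12)/gamma, the Coulomb
operator g12 = 1/r12, and the strong-orthogonality projector
Q12 = (1 - o1)(1 - o2)(1 - v1 v2). The geminal sign follows the standard
convention: its coalescence expansion -1/gamma + r12 - ... produces the
s-wave cusp with the *positive* fixed amplitudes 3/8 (s) and 1/8 (p) of the
rational generator, which enter the energy only through the fixed
coefficients

    E_F12 = 5/4 V_ij^ij - 1/4 V_ji^ij + 7/32 B(1) + 1/32 B_ji^ij
            - (eps_i + eps_j) [7/32 X(1) + 1/32 X_ji^ij].

The "(1)" slots use the direct pattern by default (`b_direct_fix=True`); the
alternative all-exchange reading of the two B coefficients is available
behind the same flag (both coincide for single-pair systems, where the
choice is unobservable). With canonical orbitals the Fock contraction of X
collapses to the (eps_i + eps_j) weighting shown; non-canonical references
are rejected rather than silently mishandled.

Generalized/extended Brillouin conditions (GBC/EBC) are applied by default:
Fock blocks between the occupied+virtual and CABS spaces are zeroed in the
union-MO basis, and every dressing that carries Fock data is built from
those MO blocks, so the production engine, the DF-only comparator and the
dense oracle all see the same effective operator.

## Evaluation strategy

Exchange-type contributions are evaluated with a hybrid of numerical
quadrature (NQ), density fitting (DF) and CABS-RI:

* V and X use the exact projector and stay entirely CABS-free: a seminumerical
  FG (resp. F^2) term, occupied-occupied and virtual-virtual products of two
  4c2e integrals (the Coulomb/geminal factor on the grid, the geminal factor
  density-fitted with its own operator metric), and two genuine 6c3e
  integrals evaluated in the AO picture with density dressings.
* B follows the reduced projector term list (verified against a brute-force
  matrix oracle on random model spaces): the f1 term through the commutator
  relation — its kinetic part is analytic, (grad F . grad F) = gamma^2 F12^2,
  and its (f+k) part one full-RI insertion; the k1, f1 o1 and o1 f1 o1
  combinations as density-dressed 6c3e contractions sharing one evaluation
  pass; and the remaining products through the U (occupied) and T (virtual)
  intermediates, whose union-space index is contracted first against
  Fock-scaled grid MOs. The (g|F|i p'') transformation is never formed.
* The formal scaling of the hybrid product path is O(N_g N_P N_p' N_i)
  (measured exponent ~4 on linear chains via operation counters); the DF-only
  comparator path is O(M^5) (measured ~5).

Products fitted with the operator's own (plain, non-robust) metric are the
variationally robust choice for products of that same operator (error
bilinear in the fit residual); when a fitted geminal factor multiplies a
grid-side Coulomb factor, the error is first order in the residual, which is
why the fixture DF sets carry wide p/d ladders.

## Integral engine

All integrals run through McMurchie-Davidson recursions with a generic
kernel interface: a kernel enters only through the derivative sequence
2^n (d/dT)^n G0(T) of its fundamental integral. Three elementary kernels
cover the family: point/Coulomb (Boys function), Gaussian (geminal
expansion terms), and Gaussian-damped Coulomb (each term of the FG
expansion retains the exact 1/r singularity). The Boys function is evaluated
through the regularized incomplete gamma function with downward recursion
(~1e-14 absolute). Angular momentum is implemented through d functions;
higher shells raise a capability error.

The Slater factor exp(-zeta r) is expanded in n Gaussians (default n = 6;
a separate fit of exp(-2 gamma r) serves F^2 rather than squaring). The
exponents come from a fixed even-tempered master sequence
0.165 * 5.5^k * zeta^2, chosen once by scanning for the smallest uniform
deviation of the 6-term model; coefficients solve a deterministic
least-squares problem on a logarithmic mesh with weight r^2. Nested models
(model n uses the first n master exponents) make the fit residual provably
non-increasing in n. Uniform accuracy is limited by the electron-electron
cusp to about 6e-3 near r -> 0 for n = 6 (a true minimax fit reaches only
~2e-3); this is a consistent redefinition of the correlation factor, shared
by every code path through one cached expansion per (zeta, n), so
cross-path validations are unaffected by it.

## Quadrature

Atom-centered grids: Mura-Knowles logarithmic radial mapping (scale 5.0
bohr), Gauss-Legendre(cos theta) x uniform(phi) angular product rules whose
algebraic degree matches the angular orders of the grid-level table
(g0: 15 radial, orders 14/38/74, up to g7: 65 radial, 110/434/1454), pruned
into inner/medium/outer regions split at {0.35, 1.0} x Bragg-Slater radius,
with three-fold iterated Becke partitioning and size adjustment. Point
totals intentionally differ from the production-code grids the level names
come from. Angular shells are generated in the molecule's principal-axes
frame, which makes all energies invariant under rigid rotations to machine
precision — except through sharp retention thresholds: a pruning cutoff can
flip borderline points between frames, changing energies at the level of
the pruning error itself (~1e-8 hartree at g0 for the water fixture).

Weight pruning drops point g when w_g max_mu |chi_mu^g|^2 falls below
threshold x the global maximum (default 1e-5). Batches hold at most 64
points (configurable), ordered along a Morton space-filling curve — a
simpler locality-preserving substitute for a Hilbert sort; ordering never
affects results, enforced to 1e-11 by the batching-invariance tests, with
per-batch partials combined by compensated summation. Per-batch AO
significance uses the actual amplitudes (exact at desk scale) rather than
extent bounds.

Shell-pair screening of grid 3c1e integrals (threshold theta_NQ, default
1e-10) uses a conservative bound: max batch weight x a bound on
int |chi_mu chi_nu| x the kernel's radial envelope at the pair-to-batch
distance; when a batch can touch the pair support, a near-field term
max|chi_mu chi_nu| x int_{|r|<1} |K| dV is added so the bound stays sound
at the 1/r singularity. Soundness is enforced by audit tests that compare
retained/dropped blocks against unscreened evaluations.

## Dense oracle

An independent contraction path guarded to <= 40 orbital-basis AOs: exact
(non-DF) MO 4c2e integrals for all kernels, mixed tensors with one union-MO
index, fine-grid (g7-level, unpruned, unscreened) quadrature for the
genuine three-electron integrals, and plain nested einsum contractions
resolved per pair. It applies the same union-space RI insertions as
production, so production-vs-oracle comparisons validate the computation,
not the intrinsic RI error. An approximate-projector V
(1 - p1 p2 - o1 p2'' - p1'' o2) is available for protocol comparisons.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| gamma | 1.3 bohr^-1 | geminal length scale |
| n_fit | 6 | Gaussians per Slater-factor expansion |
| grid_level | g2 | production grid (g0..g4, g7) |
| theta_nq | 1e-10 | 3c1e shell-pair screening threshold |
| weight_threshold | 1e-5 | grid-point retention threshold |
| batch_grid / batch_aux / batch_mo | 64 / 16 / 16 | batching caps |
| commutator_level | full | include the gamma^2 F2 and (f+k) add-ons of B |
| frozen_core | 0 | occupied orbitals excluded from the active pairs |
| Loewdin drop | 1e-8 | union-overlap eigenvalue truncation for CABS |
| DF metric drop | 1e-10 (relative) | metric pseudo-inversion truncation |

All paths are deterministic; there is no random number source outside the
test-only model-space draws.

## Fixtures: what they do and do not show

The bundled systems (He, H2 at 0.74 A, water, linear H chains, a
pseudo-glycine repeat chain) use small even-tempered bases with CABS and DF
auxiliaries covering s/p/d. They exercise every code path — CABS spans,
d-function integrals, frozen-core bookkeeping, scaling probes — at desk
scale. They do *not* emulate production basis sets (correlation-consistent
F12 sets with optimized CABS/MP2fit partners), so absolute corrections are
not literature values; cross-path agreement (production vs oracle, hybrid
vs DF-only, screened vs unscreened) is what the tests establish. Chain
fixtures grow strictly linearly in atoms, AOs, electrons and grid points,
which is what makes counter-based scaling exponents clean (~4.0 vs 5.0).

Reference protocol for grid-convergence measurements: the same NQ/DF/CABS-RI
pipeline on the g7 grid with screening and pruning off. Against this
reference the water staircase decreases monotonically
(g0..g4: ~341, 136, 5.8, 0.74, 0.15 uEh). For H2 the fixture is so soft
that every level is already within 0.52 uEh, and the assembled energy shows
one inversion (g0: 0.36 vs g1: 0.52 uEh) caused by signed cancellation
between terms — every individual quadrature term and each intermediate
(V, X, B) converges strictly monotonically over four orders of magnitude.
Quadrature-error monotonicity of a sum of signed terms is not a theorem,
and the corresponding acceptance check is left failing for H2 rather than
widened.

## Known limitations

* Closed-shell singlets, canonical orbitals, cartesian Gaussians up to d.
* Dense algebra throughout; no block-sparse exploitation, so the AO-picture
  paths are quadratic-to-quartic at desk scale rather than linear scaling.
* The dense oracle (and the optional MP2 helper) hold full 4-index tensors
  and are guarded to 40 AOs.
* The DF-only comparator exists for cross-checking and counter comparisons,
  not as an optimized production path.
* Uniform STG-fit accuracy is cusp-limited (see above); n_fit >= 9 reduces
  it at the cost of fit conditioning.
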