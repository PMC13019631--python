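# f12quad

Seminumerical evaluation of the exchange-type intermediates of the
explicitly correlated MP2-F12(3C/FIX) correction, combining numerical
quadrature (NQ), density fitting (DF) and the complementary-auxiliary-basis
(CABS) resolution of the identity — together with a dense brute-force
oracle so that every reformulated contraction can be validated on small
closed-shell molecules.

## Who this is for

Electronic-structure method developers who want a compact, fully validated
reference implementation of the hybrid NQ/DF/CABS-RI route to the V, X and
B intermediates: the formulation reduces the formal cost of the products of
two 4c2e integrals from O(M^5) (pure density fitting) to O(M^4), which this
package demonstrates in operation *counts* on linear chains rather than
wall time.

## The model

With a closed-shell RHF reference, canonical orbitals, the Slater geminal
F12 = -exp(-gamma r12)/gamma and the strong-orthogonality projector
Q12 = (1-o1)(1-o2)(1-v1v2), the fixed-amplitude correction is

    E_F12 = 5/4 V_ij^ij - 1/4 V_ji^ij + 7/32 B(1) + 1/32 B_ji^ij
            - (eps_i+eps_j) [7/32 X(1) + 1/32 X_ji^ij]

with V = <ij|F Q g|kl>, X = <ij|F Q F|kl>, B = <ij|F Q (f1+f2) Q F|kl>
summed over active pairs. V and X are evaluated with the *exact* projector,
entirely CABS-free: a seminumerical FG/F^2 term, occ-occ and virt-virt
products of 4c2e integrals (one factor on the grid, the geminal factor
density-fitted), and two genuine six-center three-electron integrals
contracted in the AO picture. B runs through a reduced operator/projector
term list (verified against a brute-force matrix oracle): a commutator
treatment of f1 (the kinetic part is analytic, (grad F)^2 = gamma^2 F^2),
density-dressed 6c3e contractions for the k1 / f1 o1 / o1 f1 o1 insertions,
and U/T intermediates whose union-space index is contracted first against
Fock-scaled grid orbitals. See `docs/methods.md` for the full account.

## Worked example

    $ f12quad compute --fixture he --grid g2 --with-mp2

prints (excerpt)

    E_F12(3C)            -0.009850078952 hartree
    E_SCF                -2.855139456593 hartree
    E_MP2                -0.027256126991 hartree
    E_MP2 + E_F12        -0.037106205943 hartree
    -- contributions (coefficient-weighted) --
    V_direct             -0.024410858494
    V_exchange            0.004882171699
    B_first               0.007651282132
    B_exchange            0.001093040305
    X_fock_first          0.000817499731
    X_fock_exchange       0.000116785676

The bundled helium fixture recovers most of the basis-set incompleteness of
its small even-tempered basis: the MP2 correlation energy moves from
-0.0273 hartree to -0.0371 hartree with the F12 correction, against a
complete-basis MP2 limit of about -0.0374 hartree. The six contribution
lines are the coefficient-weighted intermediates of the energy formula
above; for a single-pair system the direct and exchange patterns coincide,
so the assembly collapses to V + B/4 - eps * X/2 exactly (one of the
acceptance checks).

Other entry points:

    f12quad oracle --fixture h2            # dense reference + deviation table
    f12quad probe-scaling --sizes 4,8      # O(M^4) vs O(M^5) counter exponents
    f12quad audit-screening --fixture h2o  # theta_NQ soundness report
    f12quad fixtures h2o                   # emit XYZ + Gaussian94 basis files

User-supplied systems take `--xyz geometry.xyz --obs obs.g94 --cabs cabs.g94
--df df.g94` (Gaussian94-style basis files, one per role).

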